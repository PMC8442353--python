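"""End-to-end study orchestration.

``run_study`` executes the three-step selection procedure on one dataset:
(1) a RESET specification check of the Poisson mean, (2) the in-sample
battery (information criteria, per-count goodness of fit, LR and Vuong
tests), (3) K-fold cross-validation against the NB2 baseline — and, when
the declared best model is a hurdle family, marginal effects and profile
probabilities.  Every artifact is written under the output directory with a
manifest recording seeds, the package version and a hash of the config.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._optimize import FitSettings
from .crossval import cv_compare, kfold_split
from .data import CountDataset, read_dataset
from .effects import average_marginal_effects, profile_probabilities, standard_profiles
from .families import FAMILIES, HURDLE_FAMILIES
from .model import CountModel, ModelSpec
from .selection import reset_test, selection_report
from .simulate import CovariateConfig, TrueDGP, default_dgp, generate_covariates, make_dataset, simulate_counts

ALL_FAMILIES = list(FAMILIES)


@dataclass
class RunConfig:
    """Configuration of a full study run."""

    # either a CSV input ...
    input: str | None = None
    outcome: str = "visits"
    covariates: list[str] | None = None
    zero_covariates: list[str] | None = None
    categorical: dict | None = None
    # ... or a synthetic block
    synthetic: dict | None = None  # {family, n, seed, [dgp overrides]}
    # stages
    models: list[str] = field(default_factory=lambda: list(ALL_FAMILIES))
    n_classes: int = 2
    J: int = 20
    K: int = 10
    cv_baseline: str = "nb2"
    cv_seed: int = 1
    bootstrap_B: int = 200
    bootstrap_seed: int = 2
    reset_powers: tuple = (2, 3, 4)
    settings: FitSettings = field(default_factory=FitSettings)
    outdir: str | None = None

    def __post_init__(self):
        unknown = [m for m in self.models if m not in FAMILIES]
        if unknown:
            raise ValueError(f"unknown model families: {unknown}")
        if self.input is None and self.synthetic is None:
            raise ValueError("config needs either an input CSV or a synthetic block")
        if isinstance(self.settings, dict):
            self.settings = FitSettings(**self.settings)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class StudyBundle:
    """All artifacts of one study run."""

    dataset: CountDataset
    reset: object
    fits: dict
    report: object
    cv: object
    best: str | None
    effects: object = None
    profiles: pd.DataFrame | None = None
    errors: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.report.table.to_csv(out / "selection_table.csv")
        self.report.tests_frame().to_csv(out / "tests.csv", index=False)
        self.report.prob_table.to_csv(out / "prob_fit_table.csv")
        self.cv.table.to_csv(out / "cv.csv", index=False)
        with open(out / "reset.json", "w") as fh:
            json.dump(self.reset.to_dict(), fh, indent=2)
        for name, fit in self.fits.items():
            fit.to_json(out / f"fit_{name}.json")
        if self.effects is not None:
            self.effects.table.to_csv(out / "marginal_effects.csv")
        if self.profiles is not None:
            self.profiles.to_csv(out / "profile_probabilities.csv")
        manifest = dict(self.manifest)
        manifest["best"] = self.best
        manifest["errors"] = {k: str(v) for k, v in self.errors.items()}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


def _load_dataset(config: RunConfig) -> CountDataset:
    if config.input is not None:
        return read_dataset(
            config.input,
            outcome=config.outcome,
            covariates=config.covariates,
            categorical=config.categorical,
            zero_covariates=config.zero_covariates,
        )
    syn = dict(config.synthetic)
    family = syn.pop("family", "hurdle_nb2")
    n = int(syn.pop("n", 2426))
    seed = int(syn.pop("seed", 0))
    covconf = CovariateConfig(n=n, seed=seed, **syn.pop("covariate_config", {}))
    if "dgp" in syn:
        dgp = TrueDGP(family=family, seed=seed + 1, **syn.pop("dgp"))
    else:
        dgp = default_dgp(family, seed=seed + 1)
    cov = generate_covariates(covconf)
    y = simulate_counts(dgp, cov)
    return make_dataset(cov, y)


def run_study(config: RunConfig) -> StudyBundle:
    """Run the whole study described by a config; never raises mid-stage.

    Stage failures are collected into the bundle's error manifest so a
    partial bundle is still written; ``bundle.ok`` reports overall success.
    """
    errors: dict[str, Exception] = {}
    dataset = _load_dataset(config)

    reset = None
    try:
        reset = reset_test(dataset, powers=config.reset_powers, settings=config.settings)
    except Exception as exc:  # noqa: BLE001
        errors["reset"] = exc

    fits = {}
    for family in config.models:
        try:
            fits[family] = CountModel(
                dataset, family, n_classes=config.n_classes, settings=config.settings
            ).fit()
        except Exception as exc:  # noqa: BLE001
            errors[f"fit:{family}"] = exc

    report = None
    try:
        report = selection_report(fits, dataset, J=config.J)
    except Exception as exc:  # noqa: BLE001
        errors["selection"] = exc

    cv = None
    try:
        folds = kfold_split(dataset.n, config.K, config.cv_seed)
        specs = [
            ModelSpec(m, n_classes=config.n_classes, settings=config.settings)
            for m in config.models
        ]
        baseline = config.cv_baseline if config.cv_baseline in config.models else config.models[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv = cv_compare(specs, dataset, folds, baseline=baseline)
    except Exception as exc:  # noqa: BLE001
        errors["cv"] = exc

    best = report.best if report is not None else None

    effects = profiles = None
    if best in HURDLE_FAMILIES:
        try:
            effects = average_marginal_effects(
                fits[best], dataset, B=config.bootstrap_B, seed=config.bootstrap_seed
            )
        except Exception as exc:  # noqa: BLE001
            errors["effects"] = exc
        try:
            prof = standard_profiles(dataset)
            profiles = profile_probabilities(fits[best], prof)
        except Exception as exc:  # noqa: BLE001
            errors["profiles"] = exc

    manifest = {
        "version": __version__,
        "config_digest": config.digest(),
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "n": dataset.n,
    }
    bundle = StudyBundle(
        dataset=dataset,
        reset=reset,
        fits=fits,
        report=report,
        cv=cv,
        best=best,
        effects=effects,
        profiles=profiles,
        errors=errors,
        manifest=manifest,
    )
    if config.outdir:
        bundle.write(config.outdir)
    return bundle
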