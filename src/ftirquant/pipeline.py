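"""End-to-end study orchestration.

The full workflow mirrors a two-component adulteration calibration
study: simulate (or load) spectra -> split calibration/test ->
screen pretreatment chains by cross-validated RMSE -> compare wavelength
selection methods on the winning chain -> fit and evaluate the final PLS
model on the held-out test set.  Every random stage draws from a named
substream of one study seed, so a config + seed pair reproduces every
number bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import MixtureDesign, NoiseModel, SpectraSet, WavenumberAxis
from .io import write_report
from .pls import CVScheme, CVResult, EvaluationReport, cross_validate, evaluate, fit_pls
from .preprocessing import FittedPreprocessor, PreprocessingSpec, fit_chain, spec_by_name, table1_specs
from .selection import (
    IRFConfig,
    MCUVEConfig,
    interval_random_frog,
    mc_uve,
    mw_pls,
    select_intervals_by_probability,
)
from .synthetic import default_design, default_profiles, planted_profiles, simulate_dataset

__all__ = [
    "PipelineConfig",
    "StudyReport",
    "split_train_test",
    "screen_preprocessing",
    "compare_selection_methods",
    "run_study",
]

# named substreams of the study seed — order is part of the contract
_STREAMS = ("simulate", "split", "screen", "mw_pls", "mc_uve", "irf", "final")


def stream_seed(seed: int, name: str) -> int:
    """Deterministic per-stage child seed derived from the study seed."""
    idx = _STREAMS.index(name)
    ss = np.random.SeedSequence(seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0]) % (2**31)


def split_train_test(
    dataset: SpectraSet,
    rule: Literal["per_level_even"] = "per_level_even",
    seed: int = 0,
    pure_adulterant: Literal["include", "exclude"] = "include",
) -> tuple[SpectraSet, SpectraSet]:
    """Split into calibration and test sets, evenly per concentration level.

    Samples at each adulteration level are shuffled (seeded) and assigned
    alternately to calibration and test, so every level contributes half
    its replicates to each subset.  Pure-adulterant (100 %) samples are
    split like any level by default; ``pure_adulterant="exclude"`` drops
    them from both subsets.
    """
    if rule != "per_level_even":
        raise ValueError(f"unknown split rule {rule!r}")
    rng = np.random.default_rng(seed)
    cal_idx: list[int] = []
    test_idx: list[int] = []
    for level in np.unique(dataset.labels):
        members = np.flatnonzero(dataset.labels == level)
        if level == 100.0 and pure_adulterant == "exclude":
            continue
        if members.size < 2:
            raise ValueError(
                f"level {level} % has only {members.size} sample(s); even split impossible"
            )
        members = rng.permutation(members)
        cal_idx.extend(int(i) for i in members[0::2])
        test_idx.extend(int(i) for i in members[1::2])
    calibration = dataset.take(sorted(cal_idx)).with_subset("calibration")
    test = dataset.take(sorted(test_idx)).with_subset("test")
    return calibration, test


def screen_preprocessing(
    dataset: SpectraSet,
    candidates: Sequence[PreprocessingSpec],
    scheme: CVScheme = 21,
    max_nlvs: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validate a PLS model under each pretreatment chain.

    Returns a table (method, nLVs, RMSECV, R2) sorted by RMSECV
    ascending with the winner flagged.  The screening set is whatever
    ``dataset`` is passed in — calibration-only for leakage hygiene, or
    the whole sample set to mirror whole-set screening workflows.
    """
    if not candidates:
        raise ValueError("no pretreatment candidates to screen")
    rows = []
    for spec in candidates:
        chain = fit_chain(spec, dataset.axis, dataset.absorbance)
        Xp = chain.transform(dataset.absorbance)
        cv = cross_validate(Xp, dataset.labels, max_nlvs, scheme, seed=seed)
        rows.append(
            {"method": spec.name, "nLVs": cv.chosen_nlvs, "RMSECV": cv.rmsecv, "R2": cv.r2}
        )
    table = pd.DataFrame(rows).sort_values("RMSECV", kind="stable").reset_index(drop=True)
    table["winner"] = False
    table.loc[0, "winner"] = True
    return table


@dataclass(frozen=True)
class SelectionStageConfig:
    mw_widths: tuple[int, ...] = (20, 40, 60)
    mw_stride: int = 1
    mcuve: MCUVEConfig = field(default_factory=MCUVEConfig)
    irf: IRFConfig = field(default_factory=IRFConfig)
    scheme: CVScheme = 5
    max_nlvs: int = 10
    irf_k_max: int = 20


def compare_selection_methods(
    calibration: SpectraSet,
    chain: FittedPreprocessor,
    methods: Sequence[str],
    cfg: SelectionStageConfig = SelectionStageConfig(),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Full-spectrum PLS versus each requested wavelength-selection method.

    Returns the comparison table (method, N.W, nLVs, RMSECV, R2) and the
    selected variable sets.  The full-spectrum column is always present.
    """
    X = chain.transform(calibration.absorbance)
    y = calibration.labels
    p = X.shape[1]
    selections: dict[str, np.ndarray] = {"full_spectrum": np.arange(p)}
    for method in methods:
        if method == "mw_pls":
            res = mw_pls(
                X, y, cfg.mw_widths, scheme=cfg.scheme, max_nlvs=cfg.max_nlvs,
                stride=cfg.mw_stride, seed=stream_seed(seed, "mw_pls"),
            )
            selections["mw_pls"] = res.selected_variables
        elif method == "mc_uve":
            mc_cfg = MCUVEConfig(
                M=cfg.mcuve.M, sampling_fraction=cfg.mcuve.sampling_fraction,
                nlvs=cfg.mcuve.nlvs, cutoff_rule=cfg.mcuve.cutoff_rule,
                scheme=cfg.mcuve.scheme, seed=stream_seed(seed, "mc_uve"),
            )
            selections["mc_uve"] = mc_uve(X, y, mc_cfg).selected
        elif method == "irf":
            irf_cfg = IRFConfig(
                interval_width=cfg.irf.interval_width, N=cfg.irf.N, Q0=cfg.irf.Q0,
                proposal_sd_factor=cfg.irf.proposal_sd_factor,
                downhill_accept_prob=cfg.irf.downhill_accept_prob,
                nlvs_cap=cfg.irf.nlvs_cap, scheme=cfg.irf.scheme,
                seed=stream_seed(seed, "irf"),
            )
            ip = interval_random_frog(X, y, irf_cfg)
            selections["irf"] = select_intervals_by_probability(
                ip, X, y, scheme=cfg.scheme, max_nlvs=cfg.max_nlvs,
                k_max=cfg.irf_k_max, seed=stream_seed(seed, "irf"),
            )
        else:
            raise ValueError(f"unknown selection method {method!r}")
    rows = []
    for name, vars_ in selections.items():
        nlv = min(cfg.max_nlvs, vars_.size)
        cv = cross_validate(X[:, vars_], y, nlv, cfg.scheme, seed=seed)
        rows.append(
            {
                "method": name,
                "N.W": int(vars_.size),
                "nLVs": cv.chosen_nlvs,
                "RMSECV": cv.rmsecv,
                "R2": cv.r2,
            }
        )
    return pd.DataFrame(rows), selections


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to re-run a study bit-identically."""

    seed: int = 0
    n_axis_points: int = 747
    profiles: Literal["default", "planted"] = "default"
    planted_window: tuple[float, float] = (1500.0, 1700.0)
    noise: NoiseModel = field(default_factory=NoiseModel)
    pure_adulterant: Literal["include", "exclude"] = "include"
    screen_on_all: bool = False  # screen pretreatments on the whole sample set
    screen_scheme: CVScheme = 21
    selection_methods: tuple[str, ...] = ("mw_pls", "mc_uve", "irf")
    selection: SelectionStageConfig = field(default_factory=SelectionStageConfig)
    final_method: str = "best"  # or one of the methods / "full_spectrum"
    final_scheme: CVScheme = "loo"
    max_nlvs: int = 10
    output_dir: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseModel(**d["noise"])
        if "selection" in d and isinstance(d["selection"], dict):
            sel = dict(d["selection"])
            if isinstance(sel.get("mcuve"), dict):
                sel["mcuve"] = MCUVEConfig(**sel["mcuve"])
            if isinstance(sel.get("irf"), dict):
                sel["irf"] = IRFConfig(**sel["irf"])
            if "mw_widths" in sel:
                sel["mw_widths"] = tuple(sel["mw_widths"])
            d["selection"] = SelectionStageConfig(**sel)
        for key in ("planted_window", "selection_methods"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class StudyReport:
    preprocessing_table: pd.DataFrame
    selection_table: pd.DataFrame
    evaluation: EvaluationReport
    winner_chain: str
    final_method: str
    final_nlvs: int
    n_selected_variables: int
    provenance: dict

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.preprocessing_table.to_csv(index=False).encode())
        h.update(self.selection_table.to_csv(index=False).encode())
        for arr in (*self.evaluation.pairs_calibration, *self.evaluation.pairs_test):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(
            json.dumps(
                [self.evaluation.rmsec, self.evaluation.rmsep,
                 self.evaluation.r2_cal, self.evaluation.r2_test,
                 self.winner_chain, self.final_method, self.final_nlvs,
                 self.n_selected_variables]
            ).encode()
        )
        return h.hexdigest()


def run_study(config: PipelineConfig, dataset: SpectraSet | None = None) -> StudyReport:
    """Execute the full workflow and return the study report.

    ``dataset`` overrides simulation (the load path); otherwise spectra
    are simulated from the default mixing design under the config's
    profiles, noise model and axis.
    """
    axis = WavenumberAxis.default(config.n_axis_points)
    if dataset is None:
        if config.profiles == "planted":
            target, adulterant = planted_profiles(axis, config.planted_window)
        else:
            target, adulterant = default_profiles()
        noise = NoiseModel(
            additive_sd=config.noise.additive_sd,
            multiplicative_slope_sd=config.noise.multiplicative_slope_sd,
            offset_sd=config.noise.offset_sd,
            baseline_poly_degree=config.noise.baseline_poly_degree,
            baseline_coeff_sd=config.noise.baseline_coeff_sd,
            seed=stream_seed(config.seed, "simulate"),
        )
        dataset = simulate_dataset(default_design(), target, adulterant, noise, axis)

    calibration, test = split_train_test(
        dataset, seed=stream_seed(config.seed, "split"),
        pure_adulterant=config.pure_adulterant,
    )

    screen_set = dataset if config.screen_on_all else calibration
    pre_table = screen_preprocessing(
        screen_set, table1_specs(), scheme=config.screen_scheme,
        max_nlvs=config.max_nlvs, seed=stream_seed(config.seed, "screen"),
    )
    winner_name = str(pre_table.loc[0, "method"])
    winner_spec = spec_by_name(winner_name)
    chain = fit_chain(winner_spec, dataset.axis, calibration.absorbance)

    sel_table, selections = compare_selection_methods(
        calibration, chain, config.selection_methods, config.selection, seed=config.seed
    )

    if config.final_method == "best":
        final_method = str(sel_table.sort_values(["RMSECV", "N.W"], kind="stable").iloc[0]["method"])
    else:
        final_method = config.final_method
    selected = selections[final_method]

    Xc = chain.transform(calibration.absorbance)
    cv = cross_validate(
        Xc[:, selected], calibration.labels,
        min(config.max_nlvs, selected.size), config.final_scheme,
        seed=stream_seed(config.seed, "final"),
    )
    model = fit_pls(Xc, calibration.labels, cv.chosen_nlvs, included_variables=selected)
    report_eval = evaluate(model, chain, calibration, test)

    cfg_dict = config.to_dict()
    provenance = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
        "package_version": __version__,
        "n_samples": int(dataset.n_samples),
        "n_calibration": int(calibration.n_samples),
        "n_test": int(test.n_samples),
    }
    report = StudyReport(
        preprocessing_table=pre_table,
        selection_table=sel_table,
        evaluation=report_eval,
        winner_chain=winner_name,
        final_method=final_method,
        final_nlvs=model.nlvs,
        n_selected_variables=int(selected.size),
        provenance=provenance,
    )
    report.provenance["report_hash"] = report.content_hash()
    if config.output_dir:
        write_report(report, config.output_dir)
    return report
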