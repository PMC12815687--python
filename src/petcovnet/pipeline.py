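"""Pipeline orchestration: simulate -> (fit) -> qc -> network -> test.

One global seed is split into per-stage substreams (stage-indexed
``numpy.random.SeedSequence`` children), so e.g. changing the permutation
count never perturbs the simulation draws.  Every stage writes a re-loadable
plain-text artifact; a manifest records the config, stage seeds and SHA-256
of every file written.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .config import HIPPOCAMPUS, CohortConfig, FrameSchedule, default_cohort_config
from .kinetics import fit_2tcm, kinetic_params_for_vt
from .network import (
    encode_covariates,
    jackknife_reference_z,
    extreme_deviation_proportion,
    participant_zscores,
    partial_correlation_matrix,
    zmatrices_to_long,
)
from .qc import run_qc
from .stats import permutation_test
from .synthetic_data import (
    simulate_demographics,
    simulate_input_function,
    simulate_regional_binding,
    simulate_tac,
)

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("simulate", "fit", "qc", "network", "test")


@dataclass
class RunConfig:
    """Config for a full reproducible run."""

    out_dir: str = "petcovnet_run"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=default_cohort_config)
    simulate_tacs: bool = False
    fit_restarts: int = 8
    fit_weights: str = "uniform"
    qc_k_sd: float = 3.0
    qc_exclude_fraction: float = 0.5
    covariates: tuple[str, ...] = ("age", "sex")
    n_perm: int = 1000
    modes: tuple[str, ...] = ("whole_brain", "hippocampus")
    contrasts: tuple[tuple[str, str], ...] = (("HC", "CHRp"), ("HC", "FEP"), ("CHRp", "FEP"))
    reference_group: str = "HC"

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "out_dir", "seed", "simulate_tacs", "fit_restarts", "fit_weights",
            "qc_k_sd", "qc_exclude_fraction", "n_perm", "reference_group",
        )}
        d["cohort"] = self.cohort.to_dict()
        d["covariates"] = list(self.covariates)
        d["modes"] = list(self.modes)
        d["contrasts"] = [list(c) for c in self.contrasts]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        for k in ("covariates", "modes"):
            if k in d:
                d[k] = tuple(d[k])
        if "contrasts" in d:
            d["contrasts"] = tuple(tuple(c) for c in d["contrasts"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _stage_seed(global_seed: int, stage: str) -> int:
    child = np.random.SeedSequence(global_seed).spawn(len(_STAGES))[_STAGES.index(stage)]
    return int(child.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, artifact: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed at {artifact}: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig, vt_table: pd.DataFrame | None = None) -> dict:
    """Execute the full pipeline and return the run report.

    ``vt_table`` short-circuits simulation/fitting ("skip-fit" mode): the
    supplied participants x ROI table feeds QC and the network stages
    directly (a participants.csv must still come from the cohort config's
    demographics or be joinable on index; here demographics are simulated
    from the same seed so ids line up).
    """
    out = pio.ensure_dir(config.out_dir)
    written: list[Path] = []
    report: dict = {"seed": config.seed, "stages": {}}

    # -- simulate ------------------------------------------------------------
    sim_seed = _stage_seed(config.seed, "simulate")
    demo = simulate_demographics(config.cohort, seed=sim_seed)
    schedule = FrameSchedule.default()
    if vt_table is None:
        vt = simulate_regional_binding(config.cohort, demo, seed=sim_seed + 1)
    else:
        vt = vt_table.copy()
        demo = demo[demo["participant_id"].isin(vt.index)].reset_index(drop=True)
    pio.write_participants(demo, out / "participants.csv")
    pio.write_vt_table(vt, out / "vt_table.csv")
    pio.write_schedule(schedule, out / "schedule.tsv")
    config.cohort.to_yaml(out / "cohort_config.yaml")
    written += [out / "participants.csv", out / "vt_table.csv", out / "schedule.tsv",
                out / "cohort_config.yaml"]
    report["stages"]["simulate"] = {"seed": sim_seed, "n_participants": len(demo)}

    # -- optional TAC simulation + fitting ------------------------------------
    if config.simulate_tacs and vt_table is None:
        fit_seed = _stage_seed(config.seed, "fit")
        inp = simulate_input_function(schedule)
        pio.write_input_function(inp, out / "input_function.tsv")
        written.append(out / "input_function.tsv")
        rng = np.random.default_rng(fit_seed)
        tac_dir = pio.ensure_dir(out / "tacs")
        rows = []
        for pid in vt.index:
            tacs = {}
            for roi in vt.columns:
                true = kinetic_params_for_vt(float(vt.at[pid, roi]))
                tacs[roi] = simulate_tac(true, inp, schedule,
                                         noise_fraction=config.cohort.noise_fraction, seed=rng)
            tac_df = pd.DataFrame(tacs)
            pio.write_tacs(schedule, tac_df, tac_dir / f"{pid}.tsv")
            written.append(tac_dir / f"{pid}.tsv")
            for roi in vt.columns:
                res = fit_2tcm(tac_df[roi].to_numpy(), inp, schedule,
                               weights=config.fit_weights, n_restarts=config.fit_restarts)
                rows.append({"participant_id": pid, "roi": roi, **{
                    "K1": res.params.K1, "k2": res.params.k2, "k3": res.params.k3,
                    "k4": res.params.k4, "Vb": res.params.Vb, "VT": res.vt,
                    "rss": res.rss, "converged": res.converged,
                }})
        fits = pd.DataFrame(rows)
        pio.write_fits(fits, out / "fits.csv")
        written.append(out / "fits.csv")
        vt = fits.pivot(index="participant_id", columns="roi", values="VT")[list(vt.columns)]
        report["stages"]["fit"] = {"seed": fit_seed, "n_fits": len(fits),
                                   "n_converged": int(fits["converged"].sum())}

    # -- qc -------------------------------------------------------------------
    try:
        vt_clean, qc_report = run_qc({"VT": vt}, k_sd=config.qc_k_sd,
                                     exclude_fraction=config.qc_exclude_fraction)
    except Exception as exc:
        raise StageError("qc", str(out / "qc_report.json"), exc) from exc
    qc_report.to_json(out / "qc_report.json")
    pio.write_vt_table(vt_clean, out / "vt_table_clean.csv")
    written += [out / "qc_report.json", out / "vt_table_clean.csv"]
    report["stages"]["qc"] = {
        "n_flagged_vt": qc_report.n_flagged("VT"),
        "n_imputed": len(qc_report.imputed_cells),
        "n_excluded": len(qc_report.excluded_participants),
    }

    # -- network ---------------------------------------------------------------
    demo_idx = demo.set_index("participant_id")
    groups = demo_idx.loc[vt_clean.index, "group"]
    cov = encode_covariates(demo, config.covariates).loc[vt_clean.index] if config.covariates else None
    hc_ids = groups.index[groups == config.reference_group]
    pat_ids = groups.index[groups != config.reference_group]
    hc_vt = vt_clean.loc[hc_ids]
    hc_cov = cov.loc[hc_ids] if cov is not None else None
    try:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            zms = participant_zscores(hc_vt, vt_clean.loc[pat_ids], hc_cov,
                                      cov.loc[pat_ids] if cov is not None else None)
            zms += jackknife_reference_z(hc_vt, hc_cov)
    except Exception as exc:
        raise StageError("network", str(out / "z_long.csv"), exc) from exc
    ref_pcc = partial_correlation_matrix(hc_vt, hc_cov)
    ref_pcc.to_csv(out / "reference_network.csv")
    z_long = zmatrices_to_long(zms, groups)
    z_long.to_csv(out / "z_long.csv", index=False)
    extreme = pd.DataFrame({zm.participant_id: extreme_deviation_proportion(zm) for zm in zms}).T
    extreme.rename_axis("participant_id").to_csv(out / "extreme_proportions.csv")
    written += [out / "reference_network.csv", out / "z_long.csv", out / "extreme_proportions.csv"]
    report["stages"]["network"] = {"n_zmatrices": len(zms), "reference_n": len(hc_ids)}

    # -- test -------------------------------------------------------------------
    test_seed = _stage_seed(config.seed, "test")
    from .network import ZMatrix, edge_subset  # local import to keep module top light

    results = []
    for mode in config.modes:
        vectors = {zm.participant_id: edge_subset(zm, mode, roi=HIPPOCAMPUS) for zm in zms}
        for a, b in config.contrasts:
            ids = [i for i in vectors if groups[i] in (a, b)]
            res = permutation_test({i: vectors[i] for i in ids},
                                   {i: groups[i] for i in ids},
                                   n_perm=config.n_perm, seed=test_seed,
                                   groups=(a, b), mode=mode)
            results.append({
                "mode": mode, "group_a": a, "group_b": b,
                "observed_stat": res.observed_stat, "p_value": res.p_value,
                "cohens_d": res.cohens_d, "n_permutations": res.n_permutations,
                "seed": res.seed,
            })
    stats_df = pd.DataFrame(results)
    stats_df.to_csv(out / "permutation_tests.csv", index=False)
    with open(out / "stats_report.json", "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=2)
    written += [out / "permutation_tests.csv", out / "stats_report.json"]
    report["stages"]["test"] = {"seed": test_seed}
    report["permutation_tests"] = results

    # -- manifest ----------------------------------------------------------------
    try:
        ver = _pkg_version("petcovnet")
    except Exception:  # noqa: BLE001 - not installed (e.g. run from a checkout)
        ver = "unknown"
    manifest = {
        "package_version": ver,
        "config": config.to_dict(),
        "stage_seeds": {s: _stage_seed(config.seed, s) for s in _STAGES},
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    report["manifest"] = str(out / "manifest.json")
    return report
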