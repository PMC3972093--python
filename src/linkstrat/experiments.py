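"""Study orchestration: simulate, analyze, stratify, and summarise.

An experiment runs one or more scenarios end to end: for every dataset,
simulate ascertained families, compute the unstratified multipoint lod in
the linkage interval containing locus B, prune on the known disease
allele (or an associated marker allele), recompute the lod, and record
the INT statistic together with the sample-size reductions.  Aggregation
produces the conditional INT summaries and power-versus-D' tables.

Scenarios:

- ``epistasis``: the four fully penetrant epistatic models (DD, DR, RD,
  RR) with a known disease allele at locus A (truth pruning).
- ``heterogeneity``: the four non-interacting counterparts (D+D, D+R,
  R+D, R+R), per-locus penetrance 0.5 -- the false-positive control.
- ``dprime-sweep``: epistatic models pruned on the associated marker
  allele for a grid of D' values (marker allele frequency matched to the
  disease allele frequency unless overridden).
- ``freq-sweep``: D' fixed while the associated marker allele frequency
  varies.

Every dataset receives a deterministically derived child seed, so a rerun
with the same master seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .int_statistic import DatasetResult, lod_threshold_table, summarize
from .linkage_engine import AnalysisModel, b_interval_grid, multipoint_lod
from .simulator import SimulationConfig, simulate_dataset
from .stratify import CarrierPredicate, prune_dataset

__all__ = [
    "ExperimentSpec",
    "run_model",
    "run_experiment",
    "power_vs_dprime",
    "DPRIME_GRID",
    "MARKER_FREQ_GRID",
]

log = logging.getLogger("linkstrat")

DPRIME_GRID = (0.0, 0.2, 0.4, 0.6, 0.8, 0.9, 1.0)
MARKER_FREQ_GRID = (0.1, 0.2, 0.3, 0.4, 0.5)

EPISTATIC_MODELS = ("DD", "DR", "RD", "RR")
HETEROGENEITY_MODELS = ("D+D", "D+R", "R+D", "R+R")


@dataclass
class ExperimentSpec:
    scenario: str  # epistasis | heterogeneity | dprime-sweep | freq-sweep
    models: tuple[str, ...] = ()
    d_prime: tuple[float, ...] = (1.0,)
    marker_freqs: tuple[float | None, ...] = (None,)  # None = matched to A
    n_datasets: int = 100
    families: int = 50
    seed: int = 0
    out_dir: str | Path | None = None
    n_interior: int = 4
    het_rule: str = "union"

    def __post_init__(self):
        known = ("epistasis", "heterogeneity", "dprime-sweep", "freq-sweep")
        if self.scenario not in known:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not self.models:
            self.models = (
                HETEROGENEITY_MODELS
                if self.scenario == "heterogeneity"
                else EPISTATIC_MODELS
            )
        if self.scenario == "dprime-sweep" and self.d_prime == (1.0,):
            self.d_prime = DPRIME_GRID
        if self.scenario == "freq-sweep" and self.marker_freqs == (None,):
            self.marker_freqs = MARKER_FREQ_GRID

    @property
    def predicate_target(self) -> str:
        # an associated-marker experiment prunes on the observed marker
        # allele; otherwise the true disease allele at A is known
        if self.scenario in ("dprime-sweep", "freq-sweep"):
            return "marker-allele"
        return "truth-at-A"


def _analyze_dataset(
    ds, cfg: SimulationConfig, analysis, predicate, positions, dataset_idx, seed
) -> DatasetResult:
    curve_u = multipoint_lod(ds, cfg.gmap, analysis, positions=positions)
    pruned, stats = prune_dataset(ds, predicate)
    if pruned:
        curve_s = multipoint_lod(pruned, cfg.gmap, analysis, positions=positions)
        lod_s = float(curve_s.lod.max())
    else:
        lod_s = 0.0  # no informative families left: no linkage evidence
    return DatasetResult(
        dataset=dataset_idx,
        lod_unstratified=float(curve_u.lod.max()),
        lod_stratified=lod_s,
        families_before=stats.families_before,
        families_after=stats.families_after,
        subjects_before=stats.subjects_before,
        subjects_after=stats.subjects_after,
        seed=seed,
    )


def run_model(
    model: str,
    n_datasets: int = 100,
    families: int = 50,
    seed: int = 0,
    d_prime: float = 1.0,
    marker_allele_freq: float | None = None,
    predicate_target: str = "truth-at-A",
    n_interior: int = 4,
    het_rule: str = "union",
) -> pd.DataFrame:
    """Run one (model, D', marker frequency) cell; returns per-dataset rows.

    Any dataset whose analysis fails is recorded with NaN lods and the
    failure reason, never silently dropped.
    """
    from .trait_models import from_name

    trait = from_name(model, het_rule=het_rule)
    cfg = SimulationConfig.from_model(
        trait,
        d_prime=d_prime,
        marker_allele_freq=marker_allele_freq,
        families_per_dataset=families,
        n_datasets=n_datasets,
    )
    analysis = AnalysisModel.matched_to_B(cfg.trait)
    if predicate_target == "marker-allele":
        predicate = CarrierPredicate.marker_allele(cfg.gmap)
    else:
        predicate = CarrierPredicate.truth_at_A(cfg.trait, cfg.gmap)
    positions = b_interval_grid(cfg.gmap, n_interior=n_interior)

    master = np.random.SeedSequence(seed)
    rows = []
    for i, child in enumerate(master.spawn(n_datasets)):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.Generator(np.random.PCG64(child))
        ds = simulate_dataset(cfg, rng)
        try:
            res = _analyze_dataset(
                ds, cfg, analysis, predicate, positions, i, child_seed
            )
            rows.append(res.as_dict())
        except Exception as exc:  # record, never silently drop
            log.warning("dataset %d failed: %s", i, exc)
            rows.append(
                {
                    "dataset": i,
                    "lod_unstratified": np.nan,
                    "lod_stratified": np.nan,
                    "int": np.nan,
                    "families_before": len(ds),
                    "families_after": 0,
                    "subjects_before": sum(p.n_members for p in ds),
                    "subjects_after": 0,
                    "seed": child_seed,
                    "error": str(exc),
                }
            )
    df = pd.DataFrame(rows)
    df.insert(0, "model", model)
    df.insert(1, "d_prime", d_prime)
    df.insert(
        2,
        "marker_freq",
        cfg.haplotypes.p_marker1 if marker_allele_freq is None else marker_allele_freq,
    )
    return df


def _cell_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def run_experiment(spec: ExperimentSpec) -> dict[str, pd.DataFrame]:
    """Run a full scenario; returns (and optionally writes) result tables.

    Returned keys: ``datasets`` (per-dataset records), ``int_summary``
    (per model/D'/frequency INT strata), ``sample_size`` (mean family and
    subject reductions), ``lod_thresholds`` (percent of datasets per lod
    cutoff), and for sweeps ``power`` (percent positive INT conditional on
    a positive unstratified lod) and ``mean_lods`` (unstratified and
    stratified means per D').
    """
    cells = []
    idx = 0
    for model in spec.models:
        for dp in spec.d_prime:
            for mf in spec.marker_freqs:
                cells.append((model, dp, mf, _cell_seed(spec.seed, idx)))
                idx += 1
    frames = []
    for model, dp, mf, cell_seed in cells:
        log.info(
            "scenario=%s model=%s d_prime=%s marker_freq=%s seed=%d",
            spec.scenario, model, dp, mf, cell_seed,
        )
        frames.append(
            run_model(
                model,
                n_datasets=spec.n_datasets,
                families=spec.families,
                seed=cell_seed,
                d_prime=dp,
                marker_allele_freq=mf,
                predicate_target=spec.predicate_target,
                n_interior=spec.n_interior,
                het_rule=spec.het_rule,
            )
        )
    datasets = pd.concat(frames, ignore_index=True)

    keys = ["model", "d_prime", "marker_freq"]
    summaries = []
    thresholds = []
    sample_size = []
    power_rows = []
    for key, sub in datasets.groupby(keys, sort=False):
        ok = sub[sub["lod_unstratified"].notna()]
        summ = summarize(ok.to_dict("records"))
        t = summ.table.reset_index()
        for col, val in zip(keys, key):
            t.insert(0, col, val)
        summaries.append(t)
        th = summ.thresholds.reset_index(names="threshold")
        for col, val in zip(keys, key):
            th.insert(0, col, val)
        thresholds.append(th)
        sample_size.append(
            dict(
                zip(keys, key),
                families_remaining_pct=100.0
                * ok["families_after"].sum()
                / ok["families_before"].sum(),
                subjects_remaining_pct=100.0
                * ok["subjects_after"].sum()
                / ok["subjects_before"].sum(),
            )
        )
        pos = ok[ok["lod_unstratified"] > 0.0]
        power_rows.append(
            dict(
                zip(keys, key),
                n_pos_lod=len(pos),
                pct_pos_int=(
                    100.0 * (pos["int"] > 0).mean() if len(pos) else np.nan
                ),
                mean_lod_unstr=ok["lod_unstratified"].mean(),
                mean_lod_str=ok["lod_stratified"].mean(),
            )
        )

    out = {
        "datasets": datasets,
        "int_summary": pd.concat(summaries, ignore_index=True),
        "lod_thresholds": pd.concat(thresholds, ignore_index=True),
        "sample_size": pd.DataFrame(sample_size),
        "power": pd.DataFrame(power_rows),
    }
    if spec.out_dir is not None:
        _write_outputs(spec, out)
    return out


def power_vs_dprime(spec: ExperimentSpec) -> pd.DataFrame:
    """Percent of datasets with INT > 0 among datasets with a positive
    unstratified lod, one row per D', one column per model."""
    if spec.scenario != "dprime-sweep":
        spec = ExperimentSpec(
            scenario="dprime-sweep",
            models=spec.models,
            d_prime=spec.d_prime if len(spec.d_prime) > 1 else DPRIME_GRID,
            n_datasets=spec.n_datasets,
            families=spec.families,
            seed=spec.seed,
            out_dir=spec.out_dir,
            n_interior=spec.n_interior,
        )
    res = run_experiment(spec)
    return res["power"].pivot_table(
        index="d_prime", columns="model", values="pct_pos_int", sort=True
    )


def _write_outputs(spec: ExperimentSpec, out: dict[str, pd.DataFrame]) -> None:
    out_dir = Path(spec.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in out.items():
        df.to_csv(out_dir / f"{name}.csv", index=False, float_format="%.6g")
    # figure data: INT distribution for datasets with unstratified lod >= 1.5
    # and mean lods against D' (rendering left to the caller)
    ds = out["datasets"]
    fig_int = ds[ds["lod_unstratified"] >= 1.5][
        ["model", "d_prime", "marker_freq", "int"]
    ]
    fig_int.to_csv(out_dir / "fig_int_distribution.csv", index=False,
                   float_format="%.6g")
    out["power"].to_csv(out_dir / "fig_lod_vs_dprime.csv", index=False,
                        float_format="%.6g")
    manifest = {
        "scenario": spec.scenario,
        "models": list(spec.models),
        "d_prime": list(spec.d_prime),
        "marker_freqs": [m for m in spec.marker_freqs],
        "n_datasets": spec.n_datasets,
        "families": spec.families,
        "seed": spec.seed,
        "het_rule": spec.het_rule,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
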