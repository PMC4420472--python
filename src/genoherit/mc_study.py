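"""Monte Carlo driver: finite-sample bias of genomic-heritability estimates.

Per replicate: simulate a blocked population, place QTL, calibrate the
trait to the target heritability, generate phenotypes, compute the true
population parameters (h2 and the genomic heritability of the marker-only
panel), subsample the estimation set, build one GRM per marker-panel
scenario and fit maximum-likelihood variance components for each.

The six scenarios are panels built from: QTL only; QTL plus the markers in
LD with them; all loci; markers in LD with QTL only; all markers (LD + LE);
and markers in LE with QTL only.  For QTL-containing panels the estimand is
the trait heritability h2 (no missing heritability when the causal variants
are typed); for marker-only panels it is the genomic heritability h2_g of
that panel; the LE-only panel tags no causal variation at all and its
estimand is ~0.

The six GRMs are assembled from three cross-product blocks (one per locus
class) via the exact partition identity ``G_AB * k_AB = G_A k_A + G_B k_B``
of the standardized-average scaling, so each replicate pays for three
matrix products instead of six.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from genoherit.synthetic_genomes import BlockSpec, GenomePopulation, simulate_population, assign_qtl
from genoherit.trait_sim import make_architecture, simulate_phenotypes
from genoherit.quantgen_params import blocked_variance_decomposition
from genoherit.grm import GRM, build_grm
from genoherit.gblup_ml import fit_ml

__all__ = [
    "SCENARIOS",
    "StudyConfig",
    "ScenarioTable",
    "run_replicate",
    "run_study",
    "aggregate",
    "rank_bias",
    "load_study_config",
]

#: Marker-panel scenarios, in presentation order.
SCENARIOS = ("QTL", "QTL+MRK.LD", "ALL", "MRK.LD", "MRK.LD+MRK.LE", "MRK.LE")

#: Scenarios whose panel contains the causal loci (estimand: trait h2).
QTL_CONTAINING = frozenset({"QTL", "QTL+MRK.LD", "ALL"})

_CLASS_OF = {
    "QTL": ("QTL",),
    "QTL+MRK.LD": ("QTL", "MRK.LD"),
    "ALL": ("QTL", "MRK.LD", "MRK.LE"),
    "MRK.LD": ("MRK.LD",),
    "MRK.LD+MRK.LE": ("MRK.LD", "MRK.LE"),
    "MRK.LE": ("MRK.LE",),
}


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one simulation design.

    ``block_design`` chooses short blocks ("SB": many 5-locus blocks, QTL
    in distinct blocks) or long blocks ("LB": fewer 50-locus blocks, QTL
    anywhere); ``transition_design`` fixed ("FTP") vs Beta-random ("RTP")
    within-block copy probabilities.  ``n_blocks`` scales the genome.
    """

    block_design: Literal["SB", "LB"] = "SB"
    transition_design: Literal["FTP", "RTP"] = "FTP"
    n_blocks: int = 2000
    n_population: int = 10_000
    n_sample: int = 1_000
    n_qtl: int = 200
    target_h2: float = 0.5
    n_replicates: int = 100
    master_seed: int = 2015
    scenarios: tuple[str, ...] = SCENARIOS
    copy_prob: float = 0.8
    copy_prob_hyper: tuple[float, float] = (8.0, 2.0)
    init_freq_range: tuple[float, float] = (0.1, 0.5)
    grm_scaling: str = "standardized_avg"

    def __post_init__(self) -> None:
        if self.n_sample > self.n_population:
            raise ValueError("n_sample cannot exceed n_population")
        unknown = set(self.scenarios) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenarios: {sorted(unknown)}")
        if self.block_design == "SB" and self.n_qtl > self.n_blocks:
            raise ValueError("SB design needs n_qtl <= n_blocks (one QTL per block)")

    @property
    def loci_per_block(self) -> int:
        return 5 if self.block_design == "SB" else 50

    @property
    def qtl_mode(self) -> str:
        return "block_random" if self.block_design == "SB" else "genome_random"

    def block_spec(self) -> BlockSpec:
        return BlockSpec(
            n_blocks=self.n_blocks,
            loci_per_block=self.loci_per_block,
            transition_mode="fixed" if self.transition_design == "FTP" else "random",
            copy_prob=self.copy_prob,
            copy_prob_hyper=self.copy_prob_hyper,
            init_freq_range=self.init_freq_range,
        )


@dataclass
class ScenarioTable:
    """Aggregated study output: per-scenario summary + per-replicate detail."""

    summary: pd.DataFrame  # index: scenario; columns: mean, sd, n_replicates
    replicates: pd.DataFrame  # one row per replicate
    config: StudyConfig | None = None


def _replicate_seedseq(master_seed: int, replicate_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(replicate_index,))


def _scenario_grms(
    sample_dosages: np.ndarray,
    pop: GenomePopulation,
    scenarios: Sequence[str],
    scaling: str,
) -> dict[str, GRM]:
    """Six GRMs from three per-class cross-products (standardized_avg only)."""
    if scaling != "standardized_avg":
        return {s: build_grm(sample_dosages, s, scaling, pop=pop) for s in scenarios}
    needed = sorted({c for s in scenarios for c in _CLASS_OF[s]})
    parts: dict[str, tuple[np.ndarray, int]] = {}
    for cls in needed:
        idx = np.flatnonzero(pop.ld_class == cls)
        X = sample_dosages[:, idx].astype(float)
        X -= X.mean(axis=0)
        sd = X.std(axis=0)
        poly = sd > 0
        W = X[:, poly] / sd[poly]
        parts[cls] = (W @ W.T, int(poly.sum()))
    out: dict[str, GRM] = {}
    for s in scenarios:
        S = None
        k = 0
        for cls in _CLASS_OF[s]:
            cp, kc = parts[cls]
            S = cp if S is None else S + cp
            k += kc
        if k == 0:
            raise ValueError(f"scenario {s!r}: no polymorphic loci in sample")
        G = S / k
        out[s] = GRM(matrix=(G + G.T) / 2.0, locus_subset=s, scaling=scaling, n_loci_used=k)
    return out


def run_replicate(config: StudyConfig, replicate_index: int) -> dict:
    """One full Monte Carlo replicate; deterministic given (seed, index)."""
    ss = _replicate_seedseq(config.master_seed, replicate_index)
    ss_genome, ss_qtl, ss_arch, ss_phen, ss_sub = ss.spawn(5)

    pop = simulate_population(config.block_spec(), config.n_population, ss_genome)
    pop = assign_qtl(pop, config.n_qtl, config.qtl_mode, np.random.default_rng(ss_qtl))
    arch = make_architecture(pop, config.target_h2, np.random.default_rng(ss_arch))
    phen = simulate_phenotypes(pop, arch, np.random.default_rng(ss_phen))

    # population parameters: h2 is exact by calibration; h2_g of the
    # marker-only panel comes from the blocked parameter algebra
    g_var = float(phen.g.var())
    sigma2_y = g_var + arch.sigma2_delta
    h2 = g_var / sigma2_y
    mrk_idx = np.flatnonzero(~pop.is_qtl)
    s2a, s2g, _ = blocked_variance_decomposition(pop, arch, mrk_idx)
    h2_g = h2 * s2g / s2a

    rng_sub = np.random.default_rng(ss_sub)
    keep = rng_sub.choice(config.n_population, size=config.n_sample, replace=False)
    y = phen.y[keep]
    y = y - y.mean()
    sample_dosages = pop.dosages[keep]

    grms = _scenario_grms(sample_dosages, pop, config.scenarios, config.grm_scaling)
    record: dict = {
        "replicate": replicate_index,
        "seed": config.master_seed,
        "h2": h2,
        "h2_g": h2_g,
        "sigma2_a": g_var,
        "sigma2_g_markers": s2g,
    }
    for s in config.scenarios:
        fit = fit_ml(y, grms[s])
        record[f"h2_hat[{s}]"] = fit.h2_u_hat
        record[f"boundary[{s}]"] = fit.boundary
    return record


def run_study(config: StudyConfig, progress: bool = False) -> ScenarioTable:
    """Run all replicates and aggregate."""
    records = []
    for r in range(config.n_replicates):
        records.append(run_replicate(config, r))
        if progress:
            print(f"replicate {r + 1}/{config.n_replicates} done", flush=True)
    return aggregate(records, config)


def aggregate(records: Sequence[dict], config: StudyConfig | None = None) -> ScenarioTable:
    """Per-scenario mean and SD (ddof=1) of the heritability estimates."""
    if len(records) < 2:
        raise ValueError("need at least 2 replicate records to aggregate")
    df = pd.DataFrame(list(records))
    est_cols = [c for c in df.columns if c.startswith("h2_hat[")]
    if config is not None:
        expected = {f"h2_hat[{s}]" for s in config.scenarios}
        if expected != set(est_cols):
            raise ValueError("records do not match the config's scenario set")
    elif df[est_cols].isna().any().any():
        raise ValueError("records have heterogeneous scenario sets (mixing error)")
    rows = []
    for c in est_cols:
        s = c[len("h2_hat[") : -1]
        vals = df[c].to_numpy(dtype=float)
        rows.append({"scenario": s, "mean": vals.mean(), "sd": vals.std(ddof=1), "n_replicates": vals.size})
    summary = pd.DataFrame(rows).set_index("scenario")
    order = [s for s in SCENARIOS if s in summary.index]
    summary = summary.loc[order]
    summary["mean_h2"] = df["h2"].mean()
    summary["mean_h2_g"] = df["h2_g"].mean()
    return ScenarioTable(summary=summary, replicates=df, config=config)


def rank_bias(table: ScenarioTable) -> pd.DataFrame:
    """Signed bias and SD per scenario, against each scenario's estimand.

    QTL-containing panels target the trait h2; marker-only panels target
    the panel's genomic heritability h2_g (~0 for the LE-only panel, whose
    estimand is reported as 0).  Missing scenarios are reported absent.
    """
    if table.replicates.empty:
        return pd.DataFrame(columns=["scenario", "estimand", "mean", "sd", "bias", "present"]).set_index("scenario")
    h2 = float(table.replicates["h2"].mean())
    h2_g = float(table.replicates["h2_g"].mean())
    rows = []
    for s in SCENARIOS:
        present = s in table.summary.index
        if not present:
            rows.append({"scenario": s, "estimand": np.nan, "mean": np.nan, "sd": np.nan, "bias": np.nan, "present": False})
            continue
        target = h2 if s in QTL_CONTAINING else (0.0 if s == "MRK.LE" else h2_g)
        mean = float(table.summary.loc[s, "mean"])
        sd = float(table.summary.loc[s, "sd"])
        rows.append({"scenario": s, "estimand": target, "mean": mean, "sd": sd, "bias": mean - target, "present": True})
    out = pd.DataFrame(rows).set_index("scenario")
    # the contrasts highlighted by the study
    attrs = {}
    if {"MRK.LD", "MRK.LD+MRK.LE"} <= set(table.summary.index):
        attrs["sd_inflation_LE_added"] = float(out.loc["MRK.LD+MRK.LE", "sd"] / out.loc["MRK.LD", "sd"])
    if {"QTL", "ALL"} <= set(table.summary.index):
        attrs["sd_inflation_ALL_vs_QTL"] = float(out.loc["ALL", "sd"] / out.loc["QTL", "sd"])
    out.attrs.update(attrs)
    return out


def load_study_config(path: str | Path) -> StudyConfig:
    """Read a StudyConfig from a YAML (or JSON) mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    for key in ("scenarios", "copy_prob_hyper", "init_freq_range"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return StudyConfig(**data)


def write_study(table: ScenarioTable, out_dir: str | Path) -> None:
    """Replicate-level TSV, summary TSV and a JSON config snapshot."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.replicates.to_csv(out / "replicates.tsv", sep="\t", index=False)
    table.summary.to_csv(out / "scenario_summary.tsv", sep="\t")
    if table.config is not None:
        import json

        (out / "config.json").write_text(json.dumps(asdict(table.config), indent=2, default=list))
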