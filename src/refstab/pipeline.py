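"""End-to-end orchestration: read -> aggregate -> per-set geNorm + NormFinder.

Each configured analysis set (by default control + type 1 carcinoma and
control + type 2 carcinoma) is analysed independently on complete-case data;
a failure in one set is recorded and the others still run.  The report
bundle carries rankings, V series, NormFinder components, recommended
normaliser sets of each configured size (top-n of the geNorm ranking, with
NormFinder alongside as corroboration), cohort summaries and a run log of
every decision taken (dropped genes, tie-breaks, variance truncations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cohort_stats, ct_io, genorm, normfinder, quantify

DEFAULT_ANALYSIS_SETS = {"type1": ["control", "EC1"], "type2": ["control", "EC2"]}


@dataclass
class AnalysisConfig:
    """Configuration of one full analysis run."""

    ct_path: str
    meta_path: str
    analysis_sets: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_ANALYSIS_SETS.items()}
    )
    efficiency: float = 2.0
    v_threshold: float = genorm.DEFAULT_V_THRESHOLD
    m_threshold: float = genorm.DEFAULT_M_THRESHOLD
    set_sizes: tuple[int, ...] = (3, 4, 5)
    max_rep_sd: float = 0.5
    layout: str = "genes-in-rows"

    def __post_init__(self):
        if self.v_threshold <= 0 or self.m_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if any(n < 2 for n in self.set_sizes):
            raise ValueError("recommended set sizes must be >= 2")

    @classmethod
    def from_yaml(cls, path, ct_path=None, meta_path=None) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            ct_path=str(ct_path or raw["ct_path"]),
            meta_path=str(meta_path or raw["meta_path"]),
            analysis_sets={
                str(k): [str(g) for g in v]
                for k, v in raw.get("analysis_sets", DEFAULT_ANALYSIS_SETS).items()
            },
            efficiency=float(raw.get("efficiency", 2.0)),
            v_threshold=float(raw.get("v_threshold", genorm.DEFAULT_V_THRESHOLD)),
            m_threshold=float(raw.get("m_threshold", genorm.DEFAULT_M_THRESHOLD)),
            set_sizes=tuple(int(n) for n in raw.get("set_sizes", (3, 4, 5))),
            max_rep_sd=float(raw.get("max_rep_sd", 0.5)),
            layout=str(raw.get("layout", "genes-in-rows")),
        )


@dataclass
class SetResult:
    """Per-analysis-set results (one group pool, e.g. control + type 1)."""

    name: str
    groups: list[str]
    n_samples: int
    dropped_genes: list[str]
    genorm: genorm.GeNormResult
    normfinder: normfinder.NormFinderFit
    recommendations: dict[int, list[str]]


@dataclass
class ReportBundle:
    sets: dict[str, SetResult]
    errors: dict[str, str]
    cohort: pd.DataFrame | None
    run_log: list[str]


def _analyse_set(name, groups, agg, meta, config, log) -> SetResult:
    subset, assignment, dropped = ct_io.build_analysis_set(agg, meta, groups)
    for g in dropped:
        log.append(f"[{name}] dropped gene {g}: missing well in subset")
    qm = quantify.relative_quantities(subset, efficiency=config.efficiency)
    gn = genorm.rank_genes(qm, v_threshold=config.v_threshold, m_threshold=config.m_threshold)
    for event in gn.tie_events:
        log.append(f"[{name}] geNorm {event}")
    if gn.optimal_n is None:
        log.append(
            f"[{name}] no V(n/n+1) below {config.v_threshold}; "
            f"advisory minimum-V n = {gn.min_v_n}"
        )
    y = quantify.log2_expression(qm)
    nf = normfinder.fit_variance_model(y, assignment)
    for event in nf.truncations:
        log.append(f"[{name}] NormFinder {event}")
    recommendations = {
        n: gn.final_ranking[:n] for n in config.set_sizes if n <= len(gn.final_ranking)
    }
    return SetResult(
        name=name,
        groups=list(groups),
        n_samples=len(subset.samples),
        dropped_genes=dropped,
        genorm=gn,
        normfinder=nf,
        recommendations=recommendations,
    )


def run_pipeline(config: AnalysisConfig) -> ReportBundle:
    """Run every configured analysis set plus the cohort descriptives."""
    log: list[str] = []
    table = ct_io.read_ct_table(config.ct_path, layout=config.layout)
    meta = ct_io.read_sample_meta(config.meta_path)
    ct_io.validate_meta_against(table.samples, meta)
    agg = ct_io.aggregate_replicates(table, max_rep_sd=config.max_rep_sd)
    n_flagged = len(agg.flags)
    if n_flagged:
        log.append(f"aggregation raised flags on {n_flagged} wells")

    sets: dict[str, SetResult] = {}
    errors: dict[str, str] = {}
    for name, groups in config.analysis_sets.items():
        try:
            sets[name] = _analyse_set(name, groups, agg, meta, config, log)
        except Exception as exc:  # one failing set must not abort the others
            errors[name] = f"{type(exc).__name__}: {exc}"
            log.append(f"[{name}] analysis failed: {errors[name]}")

    cohort = None
    if {"age", "bmi"}.issubset(meta.columns) and meta[["age", "bmi"]].notna().all().all():
        try:
            cohort = cohort_stats.cohort_table(meta)
        except ValueError as exc:
            log.append(f"cohort summary skipped: {exc}")
    else:
        log.append("cohort summary skipped: metadata lacks complete age/bmi")
    return ReportBundle(sets=sets, errors=errors, cohort=cohort, run_log=log)


def _summary_dict(bundle: ReportBundle) -> dict:
    out: dict = {"analysis_sets": {}, "errors": bundle.errors, "run_log": bundle.run_log}
    for name, res in bundle.sets.items():
        nf = res.normfinder
        out["analysis_sets"][name] = {
            "groups": res.groups,
            "n_samples": res.n_samples,
            "dropped_genes": res.dropped_genes,
            "genorm": {
                "final_ranking": res.genorm.final_ranking,
                "m_values": {g: res.genorm.m_values[g] for g in res.genorm.final_ranking},
                "stable_genes": res.genorm.stable_genes,
                "v_series": [[n, v] for n, v in res.genorm.v_series],
                "optimal_n": res.genorm.optimal_n,
                "min_v_n": res.genorm.min_v_n,
            },
            "normfinder": {
                "ranking": nf.ranking,
                "stability": {g: nf.rho[g] for g in nf.ranking},
                "best_gene": nf.best_gene,
                "best_pair": list(nf.best_pair) if nf.best_pair else None,
                "best_pair_stability": nf.best_pair_stability,
                "tau2": nf.tau2,
            },
            "recommendations": {str(n): genes for n, genes in res.recommendations.items()},
        }
    if bundle.cohort is not None:
        out["cohort"] = bundle.cohort.round(6).to_dict(orient="records")
    return out


def write_report(bundle: ReportBundle, outdir) -> list[Path]:
    """Write the deterministic report file set; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    ranking_frames, v_frames, nf_frames = [], [], []
    for name, res in bundle.sets.items():
        rf = res.genorm.ranking_frame()
        rf.insert(0, "analysis_set", name)
        ranking_frames.append(rf)
        vf = res.genorm.v_frame()
        vf.insert(0, "analysis_set", name)
        v_frames.append(vf)
        sf = res.normfinder.stability_frame()
        sf.insert(0, "analysis_set", name)
        nf_frames.append(sf)
    for frames, fname in (
        (ranking_frames, "genorm_ranking.csv"),
        (v_frames, "genorm_v_series.csv"),
        (nf_frames, "normfinder_stability.csv"),
    ):
        if frames:
            path = outdir / fname
            pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")
            written.append(path)

    if bundle.cohort is not None:
        path = outdir / "cohort_summary.csv"
        bundle.cohort.to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    summary = _summary_dict(bundle)
    json_path = outdir / "summary.json"
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(json_path)

    lines = ["Reference-gene stability report", "=" * 33, ""]
    for name, res in bundle.sets.items():
        gn = res.genorm
        lines.append(f"Analysis set '{name}' ({' + '.join(res.groups)}, n={res.n_samples}):")
        lines.append(f"  geNorm ranking (most stable first): {', '.join(gn.final_ranking)}")
        opt = gn.optimal_n if gn.optimal_n is not None else f"none below threshold (min-V n={gn.min_v_n})"
        lines.append(f"  optimal number of reference genes: {opt}")
        for n, genes in sorted(res.recommendations.items()):
            lines.append(f"  recommended {n}-gene normaliser: {', '.join(sorted(genes))}")
        nf = res.normfinder
        pair = " + ".join(nf.best_pair) if nf.best_pair else "n/a"
        lines.append(
            f"  NormFinder best gene: {nf.best_gene} "
            f"(stability {nf.rho[nf.best_gene]:.3f}); best pair: {pair}"
        )
        lines.append("")
    for name, msg in bundle.errors.items():
        lines.append(f"Analysis set '{name}' FAILED: {msg}")
    txt_path = outdir / "summary.txt"
    txt_path.write_text("\n".join(lines) + "\n")
    written.append(txt_path)

    log_path = outdir / "run_log.txt"
    log_path.write_text("\n".join(bundle.run_log) + "\n")
    written.append(log_path)
    return written
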