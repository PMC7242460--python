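"""Reading, validation and aggregation of qRT-PCR threshold-cycle (Ct) tables.

The on-disk convention is a wide matrix with genes in rows and one column per
technical replicate, named ``<sample>_r1 .. _rK`` (the suffix is configurable).
Non-numeric cells (``Undetermined``, blanks) are recorded as missing, never
silently dropped.  Aggregation collapses technical replicates to a per-well
mean Ct plus a replicate SD, attaching QC flags instead of discarding data.
"""

from __future__ import annotations

import csv
import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Upper bound of a plausible threshold cycle on a 40-45 cycle run.
CT_MAX = 45.0
#: Ct at or above which a well is flagged as a non-detect (kept, never truncated).
DEFAULT_NONDETECT_CT = 40.0

_MISSING_TOKENS = {"", "undetermined", "na", "nan", "n/a", "none"}

META_COLUMNS = ["sample_id", "group", "subgroup", "age", "bmi"]


class CtParseError(ValueError):
    """Raised for malformed Ct tables (ragged rows, duplicate symbols, bad cells)."""


@dataclass
class CtTable:
    """Per-gene, per-sample, per-replicate threshold-cycle values.

    Parameters
    ----------
    genes, samples : list of str
        Ordered gene symbols and sample identifiers.
    ct : ndarray of shape (n_genes, n_samples, replicate_count)
        Threshold cycles in PCR cycles; NaN marks a missing well.
    replicate_count : int
        Expected technical replicates per well (3 in a standard TaqMan run).
    """

    genes: list[str]
    samples: list[str]
    ct: np.ndarray
    replicate_count: int = 3

    def __post_init__(self) -> None:
        self.ct = np.asarray(self.ct, dtype=float)
        expected = (len(self.genes), len(self.samples), self.replicate_count)
        if self.ct.shape != expected:
            raise ValueError(f"ct array has shape {self.ct.shape}, expected {expected}")
        if len(set(self.genes)) != len(self.genes):
            raise CtParseError("duplicate gene symbols in CtTable")
        if len(set(self.samples)) != len(self.samples):
            raise CtParseError("duplicate sample ids in CtTable")
        finite = self.ct[np.isfinite(self.ct)]
        if finite.size and (np.any(finite <= 0) or np.any(finite > CT_MAX)):
            raise ValueError(f"Ct values must lie in (0, {CT_MAX}] cycles")

    @property
    def n_wells(self) -> int:
        """Total number of reaction wells (genes x samples x replicates)."""
        return self.ct.size

    def to_frame(self) -> pd.DataFrame:
        """Wide genes-in-rows frame with ``<sample>_r<k>`` columns."""
        cols = [f"{s}_r{r + 1}" for s in self.samples for r in range(self.replicate_count)]
        flat = self.ct.reshape(len(self.genes), -1)
        return pd.DataFrame(flat, index=pd.Index(self.genes, name="gene"), columns=cols)


@dataclass
class AggregatedCt:
    """Replicate-collapsed Ct values with QC flags.

    ``mean_ct`` and ``rep_sd`` are genes x samples frames; ``flags`` maps a
    ``(gene, sample)`` well to the set of QC flags raised for it
    (``missing``, ``single-replicate``, ``noisy-replicates``, ``non-detect``).
    """

    genes: list[str]
    samples: list[str]
    mean_ct: pd.DataFrame
    rep_sd: pd.DataFrame
    flags: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)

    def well_flags(self, gene: str, sample: str) -> frozenset[str]:
        return self.flags.get((gene, sample), frozenset())

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: gene, sample, mean_ct, rep_sd, flags."""
        rows = []
        for g in self.genes:
            for s in self.samples:
                rows.append(
                    {
                        "gene": g,
                        "sample": s,
                        "mean_ct": self.mean_ct.at[g, s],
                        "rep_sd": self.rep_sd.at[g, s],
                        "flags": ";".join(sorted(self.well_flags(g, s))),
                    }
                )
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _delimiter_for(path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".txt")) else ","


def _parse_cell(raw: str, row_idx: int) -> float:
    token = raw.strip()
    if token.lower() in _MISSING_TOKENS:
        return np.nan
    try:
        value = float(token)
    except ValueError as exc:
        raise CtParseError(f"cannot parse Ct cell {raw!r} in row {row_idx}") from exc
    return value


def _split_replicate_column(name: str, suffix: str) -> tuple[str, int]:
    m = re.fullmatch(rf"(?P<sample>.+){re.escape(suffix)}(?P<rep>\d+)", name)
    if m is None:
        raise CtParseError(
            f"column {name!r} does not follow the '<sample>{suffix}<k>' replicate convention"
        )
    return m.group("sample"), int(m.group("rep"))


def read_ct_table(
    path,
    layout: str = "genes-in-rows",
    replicate_suffix: str = "_r",
) -> CtTable:
    """Read a wide CSV/TSV Ct matrix into a :class:`CtTable`.

    ``layout`` is either ``genes-in-rows`` (rows are genes, columns are
    ``<sample>_r<k>`` wells) or ``samples-in-rows`` (the transpose: rows are
    ``<sample>_r<k>``, columns are genes).  The dialect is sniffed from the
    extension; decimal points only.
    """
    if layout not in ("genes-in-rows", "samples-in-rows"):
        raise ValueError(f"unknown layout {layout!r}")
    delim = _delimiter_for(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter=delim)]
    if not rows:
        raise CtParseError(f"{path}: empty file")
    header = rows[0]
    width = len(header)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise CtParseError(f"{path}: ragged row {i} ({len(row)} fields, expected {width})")

    row_labels = [r[0].strip() for r in rows[1:]]
    col_labels = [h.strip() for h in header[1:]]
    values = np.array(
        [[_parse_cell(cell, i + 2) for cell in row[1:]] for i, row in enumerate(rows[1:])],
        dtype=float,
    ).reshape(len(row_labels), len(col_labels))

    if layout == "samples-in-rows":
        well_labels, genes, matrix = row_labels, col_labels, values.T
    else:
        well_labels, genes, matrix = col_labels, row_labels, values
    # matrix is genes x wells from here on

    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise CtParseError(f"duplicate gene symbol(s): {', '.join(dupes)}")

    parsed = [_split_replicate_column(w, replicate_suffix) for w in well_labels]
    samples: list[str] = []
    for s, _ in parsed:
        if s not in samples:
            samples.append(s)
    rep_count = max(r for _, r in parsed)
    seen: set[tuple[str, int]] = set()
    for key in parsed:
        if key in seen:
            raise CtParseError(f"duplicate well column for sample {key[0]!r} replicate {key[1]}")
        seen.add(key)

    ct = np.full((len(genes), len(samples), rep_count), np.nan)
    sample_idx = {s: i for i, s in enumerate(samples)}
    for col, (s, r) in enumerate(parsed):
        ct[:, sample_idx[s], r - 1] = matrix[:, col]

    table = CtTable(genes=genes, samples=samples, ct=ct, replicate_count=rep_count)
    for gi, g in enumerate(genes):
        if np.all(np.isnan(ct[gi])):
            warnings.warn(f"gene {g!r} has no detected wells", stacklevel=2)
    return table


def write_ct_table(table: CtTable, path) -> None:
    """Write a genes-in-rows CSV/TSV that :func:`read_ct_table` round-trips losslessly."""
    delim = _delimiter_for(path)
    cols = [f"{s}_r{r + 1}" for s in table.samples for r in range(table.replicate_count)]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(["gene", *cols])
        flat = table.ct.reshape(len(table.genes), -1)
        for g, row in zip(table.genes, flat):
            writer.writerow(
                [g] + ["Undetermined" if np.isnan(v) else format(float(v), ".17g") for v in row]
            )


def read_sample_meta(path) -> pd.DataFrame:
    """Read the sample metadata table (sample_id, group, subgroup, age, bmi)."""
    delim = _delimiter_for(path)
    meta = pd.read_csv(path, sep=delim)
    missing = [c for c in ("sample_id", "group") if c not in meta.columns]
    if missing:
        raise CtParseError(f"metadata is missing required column(s): {', '.join(missing)}")
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise CtParseError(f"duplicate sample_id(s) in metadata: {dupes}")
    if meta["group"].isna().any():
        raise CtParseError("metadata contains samples with no group label")
    return meta


def validate_meta_against(table_samples: list[str], meta: pd.DataFrame) -> None:
    """Every sample in the Ct table must carry a metadata row."""
    known = set(meta["sample_id"])
    orphans = [s for s in table_samples if s not in known]
    if orphans:
        raise CtParseError(f"samples without metadata rows: {orphans}")


def aggregate_replicates(
    ct: CtTable,
    max_rep_sd: float = 0.5,
    nondetect_ct: float = DEFAULT_NONDETECT_CT,
) -> AggregatedCt:
    """Collapse technical replicates to mean Ct and replicate SD per well.

    The mean is the arithmetic mean of non-missing replicate Ct values (the
    scale on which instrument noise is approximately additive); the SD uses
    the n-1 denominator.  Wells are flagged, never dropped: ``noisy-replicates``
    when the replicate SD exceeds ``max_rep_sd`` cycles, ``single-replicate``
    when only one replicate amplified, ``missing`` when none did, and
    ``non-detect`` when the mean Ct reaches ``nondetect_ct``.
    """
    if max_rep_sd <= 0:
        raise ValueError("max_rep_sd must be positive")
    n_g, n_s = len(ct.genes), len(ct.samples)
    mean = np.full((n_g, n_s), np.nan)
    sd = np.full((n_g, n_s), np.nan)
    flags: dict[tuple[str, str], frozenset[str]] = {}
    for gi, g in enumerate(ct.genes):
        for si, s in enumerate(ct.samples):
            reps = ct.ct[gi, si]
            good = reps[np.isfinite(reps)]
            well_flags: set[str] = set()
            if good.size == 0:
                well_flags.add("missing")
            else:
                mean[gi, si] = good.mean()
                if good.size == 1:
                    sd[gi, si] = 0.0
                    well_flags.add("single-replicate")
                else:
                    sd[gi, si] = good.std(ddof=1)
                    if sd[gi, si] > max_rep_sd:
                        well_flags.add("noisy-replicates")
                if mean[gi, si] >= nondetect_ct:
                    well_flags.add("non-detect")
            if well_flags:
                flags[(g, s)] = frozenset(well_flags)
    idx = pd.Index(ct.genes, name="gene")
    cols = pd.Index(ct.samples, name="sample")
    return AggregatedCt(
        genes=list(ct.genes),
        samples=list(ct.samples),
        mean_ct=pd.DataFrame(mean, index=idx, columns=cols),
        rep_sd=pd.DataFrame(sd, index=idx, columns=cols),
        flags=flags,
    )


def build_analysis_set(
    agg: AggregatedCt,
    meta: pd.DataFrame,
    groups: list[str],
) -> tuple[AggregatedCt, pd.Series, list[str]]:
    """Restrict an aggregated table to the samples of the requested groups.

    Returns the restricted :class:`AggregatedCt`, a per-sample group
    assignment, and the list of genes dropped because a retained sample was
    missing (complete-case per analysis set; both geNorm normalisation
    factors and NormFinder sample-centering require a full matrix).
    """
    validate_meta_against(agg.samples, meta)
    group_of = dict(zip(meta["sample_id"], meta["group"]))
    present = set(group_of.values())
    unknown = [g for g in groups if g not in present]
    if unknown:
        raise ValueError(f"group label(s) {unknown} not present in metadata")
    keep = [s for s in agg.samples if group_of[s] in set(groups)]
    if not keep:
        raise ValueError("no samples match the requested groups")
    assignment = pd.Series({s: group_of[s] for s in keep}, name="group").loc[keep]
    counts = assignment.value_counts()
    small = [g for g in groups if counts.get(g, 0) < 2]
    if small:
        raise ValueError(f"group(s) {small} have fewer than 2 samples in the analysis set")

    sub_mean = agg.mean_ct[keep]
    complete = sub_mean.notna().all(axis=1)
    dropped = [g for g in agg.genes if not complete[g]]
    kept_genes = [g for g in agg.genes if complete[g]]
    for g in dropped:
        logger.info("analysis set %s: gene %s dropped (missing well in subset)", groups, g)
    if dropped and len(dropped) > 0.25 * len(agg.genes):
        warnings.warn(
            f"{len(dropped)} of {len(agg.genes)} genes dropped for groups {groups}",
            stacklevel=2,
        )
    restricted = AggregatedCt(
        genes=kept_genes,
        samples=keep,
        mean_ct=agg.mean_ct.loc[kept_genes, keep],
        rep_sd=agg.rep_sd.loc[kept_genes, keep],
        flags={k: v for k, v in agg.flags.items() if k[0] in set(kept_genes) and k[1] in set(keep)},
    )
    return restricted, assignment, dropped
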