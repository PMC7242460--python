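"""Seeded synthetic qRT-PCR Ct datasets with known ground-truth stability.

The generative model works on the Ct scale (the log scale of template
abundance, where qPCR noise is approximately Gaussian):

    Ct(i, g, j, r) = B_i + d_ig + a_gj + b_igj + e_igjr

with gene baseline B_i, systematic group shift d_ig (zero-sum across groups
for group-regulated genes), a sample-wide abundance effect a_gj shared by all
genes (mimicking RNA input differences; invisible to ratio- or
centering-based stability methods), intragroup biological noise b_igj with
per-gene SD sigma_ig, and technical replicate noise e_igjr with SD tau.

The default design mirrors a 32-gene reference panel measured in triplicate
on 9 control, 9 type 1 and 6 type 2 carcinoma samples, with graded stability
tiers so the designed ranking is recoverable.  Independent random substreams
drive the abundance, biology, replicate and metadata draws, so changing one
noise source leaves the other draws untouched at a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .ct_io import CtTable

DEFAULT_GROUP_SIZES = {"control": 9, "EC1": 9, "EC2": 6}
DEFAULT_SUBGROUPS = {
    "control": ["atrophic", "secretory", "proliferative"],
    "EC1": ["grade1", "grade2", "grade3"],
    "EC2": ["serous", "carcinosarcoma"],
}
# age / BMI sampling distributions per group (mean, SD), matching the cohort
_AGE_DIST = {"control": (51.9, 8.5), "EC1": (72.8, 11.4), "EC2": (54.5, 6.2)}
_BMI_DIST = {"control": (26.2, 3.4), "EC1": (32.4, 5.1), "EC2": (37.2, 4.4)}
_AGE_DEFAULT = (55.0, 10.0)
_BMI_DEFAULT = (27.0, 4.0)

TIERS = ("stable", "moderate", "unstable", "group-regulated")

# panel symbols ordered most stable -> least stable in the default design
_PANEL = [
    "IPO8", "PUM1", "PSMC4", "ELF1", "EIF2B1", "B2M", "MRPL19", "RPS17",
    "PPIA", "YWHAZ", "GUSB", "PGK1", "POP4", "CASC3", "CDKN1B", "GAPDH",
    "UBC", "RPL37A", "CDKN1A", "HMBS", "GADD45A", "ABL1", "HPRT1", "TFRC",
    "POLR2A", "PES1", "RPLP0", "TBP", "ACTB", "18S", "MT-ATP6", "RPL30",
]

# group-regulated overrides: zero-sum Ct shifts across the three groups
_REGULATED_SHIFTS = {
    "GADD45A": {"control": -1.0, "EC1": 0.5, "EC2": 0.5},
    "CDKN1A": {"control": 1.2, "EC1": -0.6, "EC2": -0.6},
    "GAPDH": {"control": -0.8, "EC1": 0.4, "EC2": 0.4},
    "TFRC": {"control": 0.6, "EC1": -0.3, "EC2": -0.3},
}


@dataclass(frozen=True)
class GeneSpec:
    """Design parameters of one simulated gene."""

    symbol: str
    baseline_ct: float
    tier: str
    sigma: dict[str, float]  # group -> intragroup SD, cycles
    shift: dict[str, float]  # group -> systematic shift d, cycles

    def __post_init__(self):
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        if any(s < 0 for s in self.sigma.values()):
            raise ValueError(f"negative sigma for gene {self.symbol}")
        shifts = list(self.shift.values())
        if any(abs(s) > 1e-12 for s in shifts) and abs(sum(shifts)) > 1e-9:
            raise ValueError(
                f"group shifts of regulated gene {self.symbol} must sum to 0 across groups"
            )


@dataclass
class SyntheticSpec:
    """Full generative description of a simulated reference-gene study."""

    genes: list[GeneSpec]
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    replicate_sd: float = 0.15
    sample_effect_sd: float = 0.5
    replicate_count: int = 3
    seed: int = 0

    def __post_init__(self):
        if not self.genes:
            raise ValueError("spec needs at least one gene")
        symbols = [g.symbol for g in self.genes]
        if len(set(symbols)) != len(symbols):
            raise ValueError("duplicate gene symbols in spec")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least 2 samples")
        if self.replicate_sd < 0 or self.sample_effect_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        for g in self.genes:
            for grp in self.group_sizes:
                if grp not in g.sigma or grp not in g.shift:
                    raise ValueError(f"gene {g.symbol} lacks parameters for group {grp!r}")

    @property
    def groups(self) -> list[str]:
        return list(self.group_sizes)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = default_spec(seed=int(raw.get("seed", 0)))
        group_sizes = {str(k): int(v) for k, v in raw.get("group_sizes", base.group_sizes).items()}
        if "genes" in raw:
            genes = [
                GeneSpec(
                    symbol=str(g["symbol"]),
                    baseline_ct=float(g.get("baseline_ct", 25.0)),
                    tier=str(g.get("tier", "moderate")),
                    sigma={k: float(v) for k, v in g["sigma"].items()},
                    shift={k: float(v) for k, v in g.get("shift", {k: 0.0 for k in group_sizes}).items()},
                )
                for g in raw["genes"]
            ]
        else:
            genes = base.genes
        return cls(
            genes=genes,
            group_sizes=group_sizes,
            replicate_sd=float(raw.get("replicate_sd", base.replicate_sd)),
            sample_effect_sd=float(raw.get("sample_effect_sd", base.sample_effect_sd)),
            replicate_count=int(raw.get("replicate_count", base.replicate_count)),
            seed=int(raw.get("seed", base.seed)),
        )


def default_spec(seed: int = 0) -> SyntheticSpec:
    """The default 32-gene, 9/9/6, triplicate study design.

    Stability tiers are graded along the panel: six designed-stable genes
    (sigma 0.15-0.30 cycles), a moderate midfield (0.40-0.90), a noisy tail
    (1.0-2.0) and four group-regulated genes with zero-sum Ct shifts between
    control and carcinoma groups.
    """
    groups = list(DEFAULT_GROUP_SIZES)
    n = len(_PANEL)
    sigmas = np.empty(n)
    tiers = []
    sigmas[:6] = np.linspace(0.15, 0.30, 6)
    sigmas[6:22] = np.linspace(0.40, 0.90, 16)
    sigmas[22:] = np.linspace(1.0, 2.0, n - 22)
    tiers = ["stable"] * 6 + ["moderate"] * 16 + ["unstable"] * (n - 22)
    genes = []
    for i, symbol in enumerate(_PANEL):
        baseline = 10.0 if symbol == "18S" else 18.0 + (3 * i) % 12
        tier = tiers[i]
        sigma = float(sigmas[i])
        shift = {g: 0.0 for g in groups}
        if symbol in _REGULATED_SHIFTS:
            tier = "group-regulated"
            sigma = 0.5
            shift = dict(_REGULATED_SHIFTS[symbol])
        genes.append(
            GeneSpec(
                symbol=symbol,
                baseline_ct=baseline,
                tier=tier,
                sigma={g: sigma for g in groups},
                shift=shift,
            )
        )
    return SyntheticSpec(genes=genes, seed=seed)


def recovery_spec(n_per_group: int = 200, seed: int = 0) -> SyntheticSpec:
    """A two-group design with known variance components, for recovery checks.

    Twelve genes spanning low to high intragroup SD, three with zero-sum
    group biases; one designed reference gene (REF: sigma 0.15 cycles, no
    bias) well separated from the runner-up (0.5 cycles) so the ranking can
    identify it — the per-sample gene-centering couples every gene's noise
    into every other's, which sets a floor no estimator can beat, and the
    design keeps the intended ordering above that floor.  Single replicates
    with zero replicate noise, so the log2-scale intragroup variance truth
    is exactly sigma^2 at E = 2.
    """
    groups = {"control": n_per_group, "EC1": n_per_group}
    zero = {g: 0.0 for g in groups}

    def gene(symbol, sigma, shift=None, tier="moderate"):
        return GeneSpec(
            symbol=symbol,
            baseline_ct=22.0,
            tier=tier,
            sigma={g: sigma for g in groups},
            shift=dict(shift) if shift else dict(zero),
        )

    genes = [
        gene("REF", 0.15, tier="stable"),
        gene("G1", 0.50),
        gene("G2", 0.60),
        gene("G3", 0.70),
        gene("B1", 0.50, {"control": -0.5, "EC1": 0.5}, tier="group-regulated"),
        gene("B2", 0.50, {"control": 0.5, "EC1": -0.5}, tier="group-regulated"),
        gene("B3", 0.60, {"control": -0.4, "EC1": 0.4}, tier="group-regulated"),
        gene("N1", 0.80, tier="unstable"),
        gene("N2", 0.90, tier="unstable"),
        gene("N3", 1.00, {"control": 0.3, "EC1": -0.3}, tier="group-regulated"),
        gene("N4", 1.10, tier="unstable"),
        gene("N5", 1.20, tier="unstable"),
    ]
    return SyntheticSpec(
        genes=genes,
        group_sizes=groups,
        replicate_sd=0.0,
        sample_effect_sd=0.5,
        replicate_count=1,
        seed=seed,
    )


def split_stability_spec(seed: int = 0, n_noisy: int = 30) -> SyntheticSpec:
    """Two near-noiseless genes among a noisy panel, study-sized (9/9/6).

    The two designed ultra-stable genes (sigma 0.02 cycles) should occupy the
    tied top rank of the geNorm elimination in almost every seeded replicate.
    """
    groups = dict(DEFAULT_GROUP_SIZES)
    zero = {g: 0.0 for g in groups}
    genes = [
        GeneSpec(f"REF{c}", 20.0, "stable", {g: 0.02 for g in groups}, dict(zero))
        for c in ("A", "B")
    ]
    noisy_sd = np.linspace(0.5, 1.5, n_noisy)
    genes += [
        GeneSpec(
            f"NSY{i:02d}", 22.0 + i % 8, "unstable",
            {g: float(noisy_sd[i]) for g in groups}, dict(zero),
        )
        for i in range(n_noisy)
    ]
    return SyntheticSpec(genes=genes, group_sizes=groups, seed=seed)


@dataclass
class GroundTruth:
    """Design parameters of a simulated dataset, for recovery checks."""

    spec: SyntheticSpec
    design_ranking: list[str]
    scores: pd.Series
    tiers: pd.Series

    def expected_sigma2_log2(self, groups: list[str] | None = None) -> pd.DataFrame:
        """True per-(gene, group) variance of replicate-averaged log2 expression.

        At 100% efficiency (E = 2) a Ct SD of sigma cycles is a log2 SD of
        sigma, and averaging R technical replicates adds tau^2/R.
        """
        groups = self.spec.groups if groups is None else list(groups)
        tau2_rep = self.spec.replicate_sd**2 / self.spec.replicate_count
        data = {
            grp: [g.sigma[grp] ** 2 + tau2_rep for g in self.spec.genes] for grp in groups
        }
        return pd.DataFrame(data, index=[g.symbol for g in self.spec.genes])

    def expected_dhat_log2(self, groups: list[str] | None = None) -> pd.DataFrame:
        """True centered intergroup differences on the log2 scale (E = 2).

        A Ct shift of d cycles is a log2 expression shift of -d; the truth is
        centered across genes per group and across groups per gene, matching
        the estimator's identifiability constraints.
        """
        groups = self.spec.groups if groups is None else list(groups)
        m = np.array([[-g.shift[grp] for grp in groups] for g in self.spec.genes])
        m = m - m.mean(axis=0, keepdims=True)
        m = m - m.mean(axis=1, keepdims=True)
        return pd.DataFrame(m, index=[g.symbol for g in self.spec.genes], columns=groups)


def truth_ranking(spec: SyntheticSpec) -> list[str]:
    """Genes ordered by designed total variability, most stable first.

    The score is the pooled intragroup SD plus the mean absolute centered
    group shift; ties are broken by symbol.  Depends only on the design, not
    the seed.
    """
    return list(_truth_scores(spec).index)


def _truth_scores(spec: SyntheticSpec) -> pd.Series:
    groups = spec.groups
    scores = {}
    for g in spec.genes:
        pooled_sd = float(np.sqrt(np.mean([g.sigma[grp] ** 2 for grp in groups])))
        shifts = np.array([g.shift[grp] for grp in groups])
        bias = float(np.abs(shifts - shifts.mean()).mean())
        scores[g.symbol] = pooled_sd + bias
    out = pd.Series(scores, name="design_score")
    return out.loc[sorted(out.index, key=lambda s: (out[s], s))]


def _subgroup_labels(group: str, n: int) -> list[str]:
    pool = DEFAULT_SUBGROUPS.get(group, [group])
    per = max(1, n // len(pool))
    labels = []
    for lab in pool:
        labels.extend([lab] * per)
    while len(labels) < n:
        labels.append(pool[len(labels) % len(pool)])
    return labels[:n]


def generate_dataset(spec: SyntheticSpec) -> tuple[CtTable, pd.DataFrame, GroundTruth]:
    """Draw one seeded dataset: Ct table, sample metadata and ground truth."""
    groups = spec.groups
    symbols = [g.symbol for g in spec.genes]
    n_genes = len(symbols)
    sizes = [spec.group_sizes[g] for g in groups]
    n_samples = sum(sizes)
    R = spec.replicate_count

    ss_abund, ss_bio, ss_rep, ss_meta = np.random.SeedSequence(spec.seed).spawn(4)
    rng_abund = np.random.default_rng(ss_abund)
    rng_bio = np.random.default_rng(ss_bio)
    rng_rep = np.random.default_rng(ss_rep)
    rng_meta = np.random.default_rng(ss_meta)

    # standard-normal draws first, scaled after, so the realised residuals are
    # identical across specs that differ only in a noise SD
    a = rng_abund.standard_normal(n_samples) * spec.sample_effect_sd
    b = rng_bio.standard_normal((n_genes, n_samples))
    e = rng_rep.standard_normal((n_genes, n_samples, R)) * spec.replicate_sd

    sample_ids, group_labels = [], []
    for grp, size in zip(groups, sizes):
        sample_ids.extend(f"{grp}_s{j + 1}" for j in range(size))
        group_labels.extend([grp] * size)

    base = np.array([g.baseline_ct for g in spec.genes])[:, None]
    shift = np.array([[g.shift[grp] for grp in group_labels] for g in spec.genes])
    sigma = np.array([[g.sigma[grp] for grp in group_labels] for g in spec.genes])
    mean_ct = base + shift + a[None, :] + sigma * b
    ct = np.clip(mean_ct[:, :, None] + e, 0.5, 44.99)

    table = CtTable(genes=symbols, samples=sample_ids, ct=ct, replicate_count=R)

    meta_rows = []
    for grp, size in zip(groups, sizes):
        subs = _subgroup_labels(grp, size)
        age_mu, age_sd = _AGE_DIST.get(grp, _AGE_DEFAULT)
        bmi_mu, bmi_sd = _BMI_DIST.get(grp, _BMI_DEFAULT)
        ages = np.clip(rng_meta.normal(age_mu, age_sd, size), 30.0, 100.0)
        bmis = np.clip(rng_meta.normal(bmi_mu, bmi_sd, size), 16.0, 60.0)
        for j in range(size):
            meta_rows.append(
                {
                    "sample_id": f"{grp}_s{j + 1}",
                    "group": grp,
                    "subgroup": subs[j],
                    "age": round(float(ages[j]), 1),
                    "bmi": round(float(bmis[j]), 1),
                }
            )
    meta = pd.DataFrame(meta_rows)

    scores = _truth_scores(spec)
    truth = GroundTruth(
        spec=spec,
        design_ranking=list(scores.index),
        scores=scores,
        tiers=pd.Series({g.symbol: g.tier for g in spec.genes}).loc[symbols],
    )
    return table, meta, truth
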