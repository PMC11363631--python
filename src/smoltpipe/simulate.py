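"""Synthetic study generator: pedigrees, genotypes, read counts, liability
phenotypes and qPCR Ct tables with the statistical structure the analysis
modules assume.

The default configuration emulates a wild x farmed common-garden design:
36 families (6 pure wild, 6 pure farmed, 24 hybrid of five cross types)
with 669 offspring in total, genotyped at a 17-SNP amplicon panel whose
founder L-allele frequencies differ by strain (landlocked near-fixed for
L, farmed mostly A, wild intermediate).  Phenotypes follow a probit
liability model with pedigree-correlated breeding values; read counts
follow a negative-binomial depth law with binomial allele sampling; Ct
tables emulate two strains x two timepoints in triplicate.

Every operation takes its randomness from ``SimConfig.seed`` via
independent spawned streams — there is no hidden global RNG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotyping import PanelLocus
from .pedigree import UNKNOWN, Pedigree
from .relatedness import additive_matrix

WILD, FARMED, LANDLOCKED, F1 = "wild", "farmed", "landlocked", "F1"

#: Cross labels of the experimental design and the strains of the two
#: parents ("F1" parents are themselves farmed x wild hybrids).
CROSS_PARENTS: dict[str, tuple[str, str]] = {
    "Wild": (WILD, WILD),
    "Farmed": (FARMED, FARMED),
    "F1-HWF": (WILD, FARMED),  # farmed mother x wild father
    "F1-HFF": (FARMED, WILD),  # farmed father x wild mother
    "F2": (F1, F1),
    "WildBC": (WILD, F1),
    "FarmedBC": (FARMED, F1),
}

#: 36-family default: 6 pure wild + 6 pure farmed + 24 hybrid families.
DEFAULT_DESIGN: dict[str, int] = {
    "Wild": 6,
    "Farmed": 6,
    "F1-HWF": 5,
    "F1-HFF": 5,
    "F2": 5,
    "WildBC": 5,
    "FarmedBC": 4,
}

# Default 17-SNP panel.  Positions on Ssa04/Chr24/Chr9/Chr3/Chr10/Chr21
# are the published panel coordinates; the remaining loci are synthetic
# placeholders.  The per-strain L-allele frequencies are loosely shaped
# like the published tables (landlocked near-fixed for L, farmed mostly
# A, wild intermediate with Ssa04 L-rich); they are simulation defaults,
# not data assertions.
_DEFAULT_PANEL_SPEC: list[tuple[str, int, str, str, float, float, float]] = [
    # chrom, pos, allele_A, allele_L, freq_L wild, farmed, landlocked
    ("Ssa04", 51770537, "T", "C", 0.79, 0.28, 1.00),
    ("Chr24", 17705276, "G", "A", 0.55, 0.45, 0.71),
    ("Chr24", 18531930, "C", "T", 0.50, 0.40, 0.42),
    ("Chr24", 40053680, "A", "G", 0.55, 0.45, 0.55),
    ("Chr9", 18646936, "G", "T", 0.00, 0.02, 1.00),
    ("Chr3", 54132443, "T", "G", 0.12, 0.02, 1.00),
    ("Chr10", 66200595, "C", "A", 0.02, 0.02, 1.00),
    ("Chr21", 18173777, "A", "C", 0.07, 0.02, 1.00),
    ("Ssa01", 10000001, "G", "C", 0.50, 0.02, 1.00),
    ("Ssa02", 20000002, "A", "T", 0.50, 0.02, 1.00),
    ("Ssa05", 30000003, "C", "G", 0.50, 0.02, 1.00),
    ("Ssa07", 40000004, "T", "A", 0.50, 0.02, 1.00),
    ("Ssa11", 50000005, "G", "A", 0.50, 0.02, 1.00),
    ("Ssa13", 60000006, "A", "G", 0.45, 0.30, 1.00),
    ("Ssa15", 70000007, "C", "T", 0.45, 0.30, 1.00),
    ("Ssa18", 80000008, "T", "C", 0.45, 0.30, 1.00),
    ("Ssa25", 90000009, "G", "T", 0.45, 0.30, 1.00),
]

DEFAULT_PANEL: list[PanelLocus] = [
    PanelLocus(c, p, a, l) for c, p, a, l, *_ in _DEFAULT_PANEL_SPEC
]

DEFAULT_FOUNDER_FREQ_L: dict[str, np.ndarray] = {
    WILD: np.array([r[4] for r in _DEFAULT_PANEL_SPEC]),
    FARMED: np.array([r[5] for r in _DEFAULT_PANEL_SPEC]),
    LANDLOCKED: np.array([r[6] for r in _DEFAULT_PANEL_SPEC]),
}


class SimConfigError(ValueError):
    """Invalid or impossible simulation configuration."""


def default_model_params() -> "ModelParams":
    """Study-like generating parameters: smoltification odds rise with
    weight, the landlocked allele at the causal locus depresses them,
    sex and interactions are null, and a moderate additive variance
    runs through the pedigree.  The intercept centers the liability at
    the 100 g mean weight so prevalence is balanced."""
    return ModelParams(
        alpha=-2.0,
        beta_G=(-0.4, -0.8),
        beta_W=0.02,
        sigma2_a=0.5,
    )


@dataclass
class ModelParams:
    """True parameters of the liability model used for forward simulation.

    Effects are on the probit liability scale; the residual variance is
    fixed at 1 and is deliberately not configurable (it is the scale
    that identifies a threshold model).  Genotype effects are relative
    to the AA reference, ordered (AL, LL).
    """

    alpha: float = 0.0
    beta_G: tuple[float, float] = (0.0, 0.0)  # (AL, LL) vs AA
    beta_W: float = 0.0  # per gram
    beta_S: float = 0.0
    beta_GW: tuple[float, float] = (0.0, 0.0)
    beta_GS: tuple[float, float] = (0.0, 0.0)
    beta_WS: float = 0.0
    sigma2_a: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma2_a < 0:
            raise SimConfigError("additive genetic variance sigma2_a must be >= 0")
        for name in ("beta_G", "beta_GW", "beta_GS"):
            v = getattr(self, name)
            if np.shape(v) != (2,):
                raise SimConfigError(f"{name} must be a pair (AL, LL effects)")


@dataclass
class CtSimParams:
    """Layout and noise law of the simulated qPCR experiment."""

    strains: tuple[str, str] = ("Gullspang", "Mowi")
    timepoints: tuple[str, str] = ("pre", "post")
    tissues: tuple[str, ...] = ("gill",)
    n_per_group: int = 10
    n_replicates: int = 3
    reference_gene: str = "ef1a"
    reference_baseline_ct: float = 18.0
    target_baseline_ct: float = 24.0
    #: gene -> {(strain, timepoint): true expression fold change vs baseline}
    fold_changes: Mapping[str, Mapping[tuple[str, str], float]] = field(
        default_factory=lambda: {
            "ncor1": {
                ("Gullspang", "pre"): 1.0,
                ("Gullspang", "post"): 0.5,
                ("Mowi", "pre"): 1.0,
                ("Mowi", "post"): 2.0,
            }
        }
    )
    noise_sd: float = 0.15  # per-replicate technical Ct noise
    sample_sd: float = 0.30  # biological sample effect shared by triplicates


@dataclass
class SimConfig:
    """Full study-generator configuration; ``seed`` is mandatory."""

    seed: int
    n_families_per_cross: int | Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_DESIGN)
    )
    cross_design: Sequence[str] = tuple(CROSS_PARENTS)
    offspring_per_family: int | None = None
    total_offspring: int | None = 669
    n_loci: int = 17
    panel: Sequence[PanelLocus] = tuple(DEFAULT_PANEL)
    founder_freq_L: Mapping[str, np.ndarray] = field(
        default_factory=lambda: dict(DEFAULT_FOUNDER_FREQ_L)
    )
    model_params: ModelParams = field(default_factory=default_model_params)
    causal_locus: str = "Ssa04:51770537"
    weight_mean: float = 100.0  # g
    weight_cv: float = 0.30
    depth_mean: float = 500.0
    depth_size: float = 5.0  # negative-binomial dispersion (size)
    seq_error: float = 0.005
    ct: CtSimParams = field(default_factory=CtSimParams)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimConfigError("seed is mandatory")
        for label in self.cross_design:
            if label not in CROSS_PARENTS:
                raise SimConfigError(
                    f"unknown cross label {label!r}; known: {sorted(CROSS_PARENTS)}"
                )
        if len(self.panel) != self.n_loci:
            raise SimConfigError(
                f"panel has {len(self.panel)} loci but n_loci = {self.n_loci}"
            )
        for strain, freqs in self.founder_freq_L.items():
            freqs = np.asarray(freqs, dtype=float)
            if freqs.shape != (self.n_loci,):
                raise SimConfigError(
                    f"founder_freq_L[{strain!r}] must have one frequency per locus"
                )
            if ((freqs < 0) | (freqs > 1)).any():
                raise SimConfigError(f"founder_freq_L[{strain!r}] outside [0, 1]")
        if not (0.0 <= self.seq_error <= 0.1):
            raise SimConfigError("seq_error must lie in [0, 0.1]")
        if self.offspring_per_family is None and self.total_offspring is None:
            raise SimConfigError("set offspring_per_family or total_offspring")
        for v, name in (
            (self.weight_mean, "weight_mean"),
            (self.weight_cv, "weight_cv"),
            (self.depth_mean, "depth_mean"),
            (self.depth_size, "depth_size"),
        ):
            if v <= 0:
                raise SimConfigError(f"{name} must be positive")

    def families(self) -> list[str]:
        """Expanded cross label per family, in deterministic order."""
        if isinstance(self.n_families_per_cross, Mapping):
            counts = self.n_families_per_cross
        else:
            counts = {label: int(self.n_families_per_cross) for label in self.cross_design}
        out: list[str] = []
        for label in self.cross_design:
            n = int(counts.get(label, 0))
            if n < 0:
                raise SimConfigError(f"negative family count for {label!r}")
            out.extend([label] * n)
        if not out:
            raise SimConfigError("design contains no families")
        return out

    def family_sizes(self) -> list[int]:
        labels = self.families()
        if self.offspring_per_family is not None:
            if self.offspring_per_family < 1:
                raise SimConfigError("offspring_per_family must be positive")
            return [int(self.offspring_per_family)] * len(labels)
        total = int(self.total_offspring)  # type: ignore[arg-type]
        if total < len(labels):
            raise SimConfigError("fewer offspring than families")
        base, extra = divmod(total, len(labels))
        return [base + 1 if i < extra else base for i in range(len(labels))]

    def _rng(self, stream: int) -> np.random.Generator:
        # independent, reproducible stream per operation
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(8)[stream])


@dataclass
class GenotypeTable:
    """Phased biallelic genotypes (1 = L allele) for a pedigree."""

    ids: list[str]
    loci: list[PanelLocus]
    haplotypes: np.ndarray  # (n_individuals, n_loci, 2) int8

    @property
    def dosage(self) -> np.ndarray:
        """Count of L alleles per individual per locus (0/1/2)."""
        return self.haplotypes.sum(axis=2)

    @property
    def calls(self) -> np.ndarray:
        return np.array(["AA", "AL", "LL"], dtype=object)[self.dosage]

    def locus_index(self, name: str) -> int:
        for i, loc in enumerate(self.loci):
            if loc.name == name or f"{loc.chrom}:{loc.pos}" == name:
                return i
        raise KeyError(f"locus {name!r} not in panel")

    def to_frame(self) -> pd.DataFrame:
        calls = self.calls
        return pd.DataFrame(
            calls, index=pd.Index(self.ids, name="id"), columns=[l.name for l in self.loci]
        ).reset_index()


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Build the multi-generation family design as an ordered pedigree.

    Each family gets its own parents: founders for pure and F1 crosses;
    for F2 and backcross families the hybrid parents are created first
    from their own founder pairs, so every F2 individual has two F1
    parents and every backcross one founder and one F1 parent.
    """
    labels = config.families()
    sizes = config.family_sizes()

    ids: list[str] = []
    sire: list[int] = []
    dam: list[int] = []
    family: list[str] = []
    cross: list[str] = []
    strain: list[str] = []
    role: list[str] = []

    def add(id_, s, d, fam, cr, st, ro) -> int:
        ids.append(id_)
        sire.append(s)
        dam.append(d)
        family.append(fam)
        cross.append(cr)
        strain.append(st)
        role.append(ro)
        return len(ids) - 1

    def make_parent(st: str, fam: str, tag: str) -> int:
        if st == F1:
            gs = add(f"{fam}.{tag}.s", UNKNOWN, UNKNOWN, fam, "founder", FARMED, "founder")
            gd = add(f"{fam}.{tag}.d", UNKNOWN, UNKNOWN, fam, "founder", WILD, "founder")
            return add(f"{fam}.{tag}", gs, gd, fam, "F1-parent", F1, "f1")
        return add(f"{fam}.{tag}", UNKNOWN, UNKNOWN, fam, "founder", st, "founder")

    counts_per_label: dict[str, int] = {}
    for label, size in zip(labels, sizes):
        k = counts_per_label.get(label, 0) + 1
        counts_per_label[label] = k
        fam = f"{label}-{k:02d}"
        st_sire, st_dam = CROSS_PARENTS[label]
        s = make_parent(st_sire, fam, "s")
        d = make_parent(st_dam, fam, "d")
        for j in range(1, size + 1):
            add(f"{fam}.o{j:03d}", s, d, fam, label, label, "offspring")

    return Pedigree(
        ids=ids,
        sire=np.array(sire),
        dam=np.array(dam),
        family=family,
        cross=cross,
        strain=strain,
        role=role,
    )


def simulate_genotypes(ped: Pedigree, config: SimConfig) -> GenotypeTable:
    """Mendelian gene drop over the pedigree.

    Founder alleles are Bernoulli(freq_L) draws from the founder's
    strain-specific frequency; every non-founder inherits one uniformly
    chosen allele from each parent, independently per locus.
    """
    rng = config._rng(1)
    n, L = ped.n, config.n_loci
    hap = np.zeros((n, L, 2), dtype=np.int8)
    freq = {k: np.asarray(v, dtype=float) for k, v in config.founder_freq_L.items()}
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            st = ped.strain[i]
            if st not in freq:
                raise SimConfigError(
                    f"founder {ped.ids[i]!r} has strain {st!r} with no founder_freq_L entry"
                )
            hap[i] = rng.random((L, 2)) < freq[st][:, None]
        elif s != UNKNOWN and d != UNKNOWN:
            hap[i, :, 0] = hap[s, np.arange(L), rng.integers(0, 2, L)]
            hap[i, :, 1] = hap[d, np.arange(L), rng.integers(0, 2, L)]
        else:  # pragma: no cover - generator never emits half-known parents
            raise SimConfigError(f"{ped.ids[i]!r} has exactly one known parent")
    return GenotypeTable(ids=list(ped.ids), loci=list(config.panel), haplotypes=hap)


def breeding_values_recursive(
    ped: Pedigree, sigma2_a: float, rng: np.random.Generator
) -> np.ndarray:
    """Breeding values by founder draw + Mendelian-sampling recursion.

    a_i = (a_s + a_d)/2 + m_i with m_i ~ N(0, sigma2_a/2); exact for
    pedigrees without inbreeding loops and O(n).
    """
    a = np.zeros(ped.n)
    if sigma2_a == 0:
        return a
    sd_f = float(np.sqrt(sigma2_a))
    sd_m = float(np.sqrt(sigma2_a / 2.0))
    for i in range(ped.n):
        s, d = ped.sire[i], ped.dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            a[i] = rng.normal(0.0, sd_f)
        else:
            mid = 0.5 * (a[s] if s != UNKNOWN else 0.0) + 0.5 * (a[d] if d != UNKNOWN else 0.0)
            a[i] = mid + rng.normal(0.0, sd_m)
    return a


def breeding_values_mvn(
    ped: Pedigree, sigma2_a: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact MVN(0, A sigma2_a) draw via Cholesky; cross-check path, O(n^3)."""
    if sigma2_a == 0:
        return np.zeros(ped.n)
    A = additive_matrix(ped).values
    Lc = np.linalg.cholesky(A + 1e-10 * np.eye(ped.n))
    return np.sqrt(sigma2_a) * (Lc @ rng.standard_normal(ped.n))


def liability_fixed_part(
    params: ModelParams, dose: np.ndarray, weight: np.ndarray, sex: np.ndarray
) -> np.ndarray:
    """alpha + beta.x for genotype dose (0/1/2 L alleles), weight (g), sex."""
    is_al = (dose == 1).astype(float)
    is_ll = (dose == 2).astype(float)
    return (
        params.alpha
        + params.beta_G[0] * is_al
        + params.beta_G[1] * is_ll
        + params.beta_W * weight
        + params.beta_S * sex
        + params.beta_GW[0] * is_al * weight
        + params.beta_GW[1] * is_ll * weight
        + params.beta_GS[0] * is_al * sex
        + params.beta_GS[1] * is_ll * sex
        + params.beta_WS * weight * sex
    )


def simulate_phenotypes(
    ped: Pedigree,
    geno: GenotypeTable,
    params: ModelParams | None = None,
    config: SimConfig | None = None,
) -> pd.DataFrame:
    """Forward-simulate the probit liability model for the offspring.

    Weights are log-normal (configured mean and CV), sexes Bernoulli(1/2),
    breeding values follow the pedigree, residuals are standard normal,
    and Y = 1 exactly when the liability exceeds zero.  The smolt score
    is emitted as 1 (non-smolt) or 5 (smolt), the binary-status extremes
    of the 1-5 visual scale.
    """
    if config is None:
        raise SimConfigError("config is required")
    params = params or config.model_params
    if params.sigma2_a < 0:
        raise SimConfigError("sigma2_a must be >= 0")
    rng = config._rng(2)

    off = np.array([r == "offspring" for r in ped.role])
    idx = np.nonzero(off)[0]
    n = idx.size

    # log-normal with the configured arithmetic mean and CV
    s2 = np.log(1.0 + config.weight_cv**2)
    mu = np.log(config.weight_mean) - s2 / 2.0
    weight = rng.lognormal(mean=mu, sigma=np.sqrt(s2), size=n)
    sex = rng.integers(0, 2, n).astype(float)

    a = breeding_values_recursive(ped, params.sigma2_a, rng)
    dose = geno.dosage[idx, geno.locus_index(config.causal_locus)]
    eta = liability_fixed_part(params, dose, weight, sex)
    liab = eta + a[idx] + rng.standard_normal(n)
    y = (liab > 0).astype(int)

    return pd.DataFrame(
        {
            "id": [ped.ids[i] for i in idx],
            "family": [ped.family[i] for i in idx],
            "cross": [ped.cross[i] for i in idx],
            "smolt_score": np.where(y == 1, 5, 1),
            "Y": y,
            "W": weight,
            "S": sex.astype(int),
            "G": np.array(["AA", "AL", "LL"], dtype=object)[dose],
            "liability": liab,
            "breeding_value": a[idx],
        }
    )


def simulate_read_counts(geno: GenotypeTable, config: SimConfig) -> pd.DataFrame:
    """Amplicon read counts per individual per panel locus.

    Informative depth is negative binomial (configured mean and size);
    the L-read count is Binomial(depth, p) with p equal to the
    sequencing-error rate, 1/2, or its complement for true AA, AL and LL
    genotypes; additional third-allele reads are a Binomial(depth,
    seq_error) overlay on top.
    """
    rng = config._rng(3)
    n, L = geno.haplotypes.shape[:2]
    size, mean = config.depth_size, config.depth_mean
    depth = rng.negative_binomial(size, size / (size + mean), size=(n, L))
    p_l = np.array([config.seq_error, 0.5, 1.0 - config.seq_error])[geno.dosage]
    n_l = rng.binomial(depth, p_l)
    n_a = depth - n_l
    n_other = rng.binomial(depth, config.seq_error)

    loci = geno.loci
    return pd.DataFrame(
        {
            "sample_id": np.repeat(geno.ids, L),
            "chrom": np.tile([l.chrom for l in loci], n),
            "pos": np.tile([l.pos for l in loci], n),
            "n_A": n_a.ravel(),
            "n_L": n_l.ravel(),
            "n_other": n_other.ravel(),
        }
    )


def simulate_ct_table(config: SimConfig) -> pd.DataFrame:
    """Triplicate qPCR Ct values for the strain x timepoint trial.

    The reference gene has a constant baseline across groups (up to
    noise); each target gene's Ct is baseline - log2(fold change) plus a
    per-sample biological effect shared by the triplicate and
    per-replicate technical noise.
    """
    rng = config._rng(4)
    ct = config.ct
    rows = []
    sample_no = 0
    for strain in ct.strains:
        for tp in ct.timepoints:
            for k in range(ct.n_per_group):
                sample_no += 1
                sid = f"{strain}_{tp}_{k + 1:02d}"
                for tissue in ct.tissues:
                    sample_eff = rng.normal(0.0, ct.sample_sd)
                    genes = {ct.reference_gene: ct.reference_baseline_ct}
                    for gene, folds in ct.fold_changes.items():
                        fold = folds.get((strain, tp), 1.0)
                        genes[gene] = ct.target_baseline_ct - np.log2(fold)
                    for gene, base in genes.items():
                        for rep in range(1, ct.n_replicates + 1):
                            noise = rng.normal(0.0, ct.noise_sd)
                            rows.append(
                                (sid, strain, tp, tissue, gene, rep, base + sample_eff + noise)
                            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "strain", "timepoint", "tissue", "gene", "replicate", "Ct"],
    )
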