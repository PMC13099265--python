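"""Synthetic data generators for every pipeline input, with planted truth.

Each generator emulates the statistical structure of the study system — a
gut microbial community with a few dominant species per enterotype, droplet
single-microbe barcodes whose purity spans the 0.5 retention threshold,
overdispersed UMI counts with planted aerobic/anaerobic expression programs
and LPMO-like markers co-expressed with the aerobic program, genome CAZyme
repertoires with controlled family copy numbers, and oxygen-graded isolate
assay readouts. Planted ground truth is returned alongside every dataset
and is never consumed by pipeline stages.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps

from .barcodes import BarcodeProfile
from .cazymes import CAZymeProfile, normalize_family
from .programs import O2_MINUS_GENES, O2_PLUS_GENES, UMIMatrix

__all__ = [
    "CommunitySimSpec",
    "CellSimSpec",
    "gen_community",
    "gen_barcode_profiles",
    "gen_umi_matrix",
    "gen_cazyme_profiles",
    "gen_assay_data",
    "default_cell_sim_spec",
]


# ---------------------------------------------------------------------------
# Community (enterotype) simulation
# ---------------------------------------------------------------------------

@dataclass
class CommunitySimSpec:
    """Planted-enterotype community specification.

    One dominant species per cluster holds a fraction of each sample drawn
    around `dominant_frac` (Beta with concentration `dominant_kappa`); the
    remaining mass is split over background species by a symmetric
    Dirichlet. The default dominance is in the range of the dominant-taxon
    medians observed in real enterotyped communities (~0.4-0.6).
    """

    n_clusters: int = 3
    n_samples: int = 40  # per cluster
    n_species: int = 40
    dominant_frac: float = 0.45
    dominant_kappa: float = 60.0
    concentration: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2 per cluster")
        if not 0.0 < self.dominant_frac < 1.0:
            raise ValueError("dominant_frac must be strictly between 0 and 1")
        if self.n_species < self.n_clusters + 1:
            raise ValueError("n_species must exceed n_clusters")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


def gen_community(spec: CommunitySimSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a samples x species relative-abundance table with planted
    enterotype labels. Rows sum to 1 within 1e-9."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    species = ([f"Dominant_{c + 1}" for c in range(spec.n_clusters)]
               + [f"sp_{i:03d}" for i in range(spec.n_species - spec.n_clusters)])
    rows, labels, sample_ids = [], [], []
    a = spec.dominant_kappa * spec.dominant_frac
    b = spec.dominant_kappa * (1.0 - spec.dominant_frac)
    for c in range(spec.n_clusters):
        for s in range(spec.n_samples):
            d = rng.beta(a, b)
            bg = rng.dirichlet(np.full(spec.n_species - 1, spec.concentration))
            row = np.empty(spec.n_species)
            row[c] = d
            others = [i for i in range(spec.n_species) if i != c]
            row[others] = bg * (1.0 - d)
            row /= row.sum()
            rows.append(row)
            labels.append(c + 1)
            sample_ids.append(f"S{c + 1}_{s:03d}")
    table = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample"),
                         columns=species)
    truth = pd.Series(labels, index=table.index, name="true_enterotype")
    return table, truth


# ---------------------------------------------------------------------------
# Barcode (single-microbe droplet) simulation
# ---------------------------------------------------------------------------

def gen_barcode_profiles(n_barcodes: int, species_pool: Sequence[str],
                         purity_beta_params: tuple[float, float] = (2.0, 1.5),
                         reads_per_barcode: int = 200,
                         seed: int = 0
                         ) -> tuple[list[BarcodeProfile], pd.DataFrame]:
    """Generate per-barcode species read-count profiles with planted purity.

    The planted majority species and purity are drawn per barcode (purity ~
    Beta, default spanning both sides of 0.5). Background species split the
    remaining mass by a Dirichlet draw capped at 0.9 * (1 - purity) per
    species (excess redistributed), so no background species can overtake
    the 0.5 retention threshold or the planted majority; reads are then
    allocated deterministically by largest-remainder rounding. The planted
    majority is therefore exactly recoverable whenever planted purity > 0.5
    (with >= 3 species in the pool), and the realized purity tracks the Beta
    draw across the 0.5 threshold; stochasticity enters through the Beta
    purity draw, the species choice and the background split.
    """
    if len(species_pool) < 2:
        raise ValueError("species_pool must contain >= 2 species")
    if reads_per_barcode < 1:
        raise ValueError("reads_per_barcode must be >= 1")
    if n_barcodes < 0:
        raise ValueError("n_barcodes must be >= 0")
    rng = np.random.default_rng(seed)
    a, b = purity_beta_params
    profiles: list[BarcodeProfile] = []
    truth_rows = []
    pool = list(species_pool)
    for i in range(n_barcodes):
        major = pool[rng.integers(len(pool))]
        purity = float(rng.beta(a, b))
        others = [s for s in pool if s != major]
        bg = rng.dirichlet(np.ones(len(others))) * (1.0 - purity)
        if len(others) >= 2:
            # keep every background species strictly below the 0.5 retention
            # threshold and below the majority; (1-p)/m floor keeps the cap
            # feasible (m shares summing to 1-p)
            m = len(others)
            cap = max((1.0 - purity) / m,
                      min(0.9 * (1.0 - purity), 0.495))
            for _ in range(len(others)):
                excess = np.maximum(bg - cap, 0.0)
                if excess.sum() <= 0:
                    break
                bg = np.minimum(bg, cap)
                free = bg < cap
                bg[free] += excess.sum() * bg[free] / max(bg[free].sum(), 1e-12)
        fractions = {major: purity}
        fractions.update({s: f for s, f in zip(others, bg)})
        # largest-remainder rounding to integer reads
        raw = {s: f * reads_per_barcode for s, f in fractions.items()}
        counts = {s: int(np.floor(v)) for s, v in raw.items()}
        short = reads_per_barcode - sum(counts.values())
        remainders = sorted(raw, key=lambda s: (raw[s] - counts[s], s),
                            reverse=True)
        for s in remainders[:short]:
            counts[s] += 1
        counts = {s: c for s, c in counts.items() if c > 0}
        profiles.append(BarcodeProfile(f"BC{i:06d}", counts))
        truth_rows.append({"barcode": f"BC{i:06d}", "true_species": major,
                           "planted_purity": purity})
    truth = pd.DataFrame(truth_rows,
                         columns=["barcode", "true_species", "planted_purity"])
    return profiles, truth


# ---------------------------------------------------------------------------
# UMI matrix simulation
# ---------------------------------------------------------------------------

@dataclass
class CellSimSpec:
    """Planted-program single-cell UMI simulation.

    Cells belong to an aerobic or anaerobic transcriptional program.
    Program genes are amplified by 2**effect_log2fc in cells of the matching
    program; LPMO-like markers are tied to aerobic membership through a
    latent Gaussian copula with target correlation `coexpression_rho`.
    Counts are negative binomial (dispersion `nb_dispersion`) on a per-cell
    log-normal library-size multiplier.
    """

    n_cells_per_program: int = 500
    gene_universe: tuple[str, ...] = ()
    program_genes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.3
    library_size_lognormal: tuple[float, float] = (0.0, 0.35)
    coexpression_rho: float = 0.6
    base_rate: float = 0.15
    n_samples: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells_per_program < 1:
            raise ValueError("n_cells_per_program must be >= 1")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not -1.0 < self.coexpression_rho < 1.0:
            raise ValueError("coexpression_rho must be in (-1, 1)")
        universe = set(self.gene_universe)
        seen: set[str] = set()
        for name, genes in self.program_genes.items():
            gs = set(genes)
            if not gs <= universe:
                raise ValueError(f"program {name!r} has genes outside the universe")
            if name != "background" and gs & seen:
                raise ValueError("program gene sets must be disjoint")
            if name != "background":
                seen |= gs
        for key in ("aerobic", "anaerobic"):
            if key not in self.program_genes:
                raise ValueError(f"program_genes must define {key!r}")


def default_cell_sim_spec(n_cells_per_program: int = 500,
                          effect_log2fc: float = 2.0,
                          coexpression_rho: float = 0.6,
                          n_background: int = 250,
                          seed: int = 0) -> CellSimSpec:
    """CellSimSpec over a single-genome universe carrying the canonical
    aerobic/anaerobic marker genes, LPMO-like markers and neutral background."""
    genome = "Ecoli_P1"
    aerobic = tuple(f"{genome}|{g}" for g in O2_PLUS_GENES)
    anaerobic = tuple(f"{genome}|{g}" for g in O2_MINUS_GENES)
    lpmo = tuple(f"{genome}|lpmo{i}" for i in range(1, 6))
    background = tuple(f"{genome}|bg{i:04d}" for i in range(n_background))
    return CellSimSpec(
        n_cells_per_program=n_cells_per_program,
        gene_universe=aerobic + anaerobic + lpmo + background,
        program_genes={"aerobic": aerobic, "anaerobic": anaerobic,
                       "lpmo": lpmo, "background": background},
        effect_log2fc=effect_log2fc,
        coexpression_rho=coexpression_rho,
        seed=seed,
    )


def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def gen_umi_matrix(spec: CellSimSpec) -> tuple[UMIMatrix, pd.DataFrame]:
    """Generate a sparse UMI matrix with planted program labels.

    Returns (UMIMatrix, cell_truth) where cell_truth records each cell's
    program, sample of origin, and latent LPMO activation.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.gene_universe)
    gidx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    programs = (["aerobic"] * spec.n_cells_per_program
                + ["anaerobic"] * spec.n_cells_per_program)
    n_cells = len(programs)
    aero = np.array([p == "aerobic" for p in programs])

    base = np.full(n_genes, spec.base_rate)
    # heterogeneous background so binning/ranking is nontrivial
    base *= rng.lognormal(0.0, 0.8, size=n_genes)

    fold = 2.0 ** spec.effect_log2fc
    aero_cols = [gidx[g] for g in spec.program_genes["aerobic"]]
    anae_cols = [gidx[g] for g in spec.program_genes["anaerobic"]]
    lpmo_cols = [gidx[g] for g in spec.program_genes.get("lpmo", ())]

    mu, sigma = spec.library_size_lognormal
    lib = rng.lognormal(mu, sigma, size=n_cells)

    # latent copula for LPMO co-expression with the aerobic program
    s = np.where(aero, 1.0, -1.0)
    s_std = (s - s.mean()) / s.std()
    rho = spec.coexpression_rho
    latent = rho * s_std + np.sqrt(1 - rho ** 2) * rng.standard_normal(n_cells)
    lpmo_activation = sps.norm.cdf(latent)  # in (0,1)

    rate = np.tile(base, (n_cells, 1)) * lib[:, None]
    rate[np.ix_(aero, aero_cols)] *= fold
    rate[np.ix_(~aero, anae_cols)] *= fold
    if lpmo_cols:
        rate[:, lpmo_cols] *= fold ** lpmo_activation[:, None]

    counts = _nb_sample(rng, rate, spec.nb_dispersion)
    cell_ids = [f"CELL{i:05d}" for i in range(n_cells)]
    sample_ids = [f"sample{(i % spec.n_samples) + 1}" for i in range(n_cells)]
    matrix = UMIMatrix(counts=sp.csr_matrix(counts), cell_ids=cell_ids,
                       feature_ids=genes, sample_ids=sample_ids)
    truth = pd.DataFrame({
        "cell": cell_ids, "program": programs, "sample": sample_ids,
        "lpmo_activation": lpmo_activation,
    })
    return matrix, truth


# ---------------------------------------------------------------------------
# CAZyme genome simulation
# ---------------------------------------------------------------------------

def _score_rule_oracle(counts: Mapping[str, int]) -> int:
    """Independent plain restatement of the screening rules, used only to
    label simulated genomes with their true score."""
    endo = counts.get("GH5", 0) + counts.get("GH8", 0)
    exo = sum(counts.get(f, 0) for f in ("GH48", "GH6", "GH7", "GH9", "GH16"))
    bglu = counts.get("GH1", 0) + counts.get("GH3", 0)
    lpmo = counts.get("AA9", 0) + counts.get("AA10", 0)
    if endo >= 1 and exo >= 1 and bglu >= 1:
        score = 1
        if lpmo >= 1:
            score += 1
        if endo >= 2:
            score += 1
        if exo >= 2:
            score += 1
        return score
    return 0


def gen_cazyme_profiles(n_genomes: int, family_rates: Mapping[str, float],
                        seed: int = 0
                        ) -> tuple[list[CAZymeProfile], pd.DataFrame]:
    """Generate genomes with Poisson CAZy-family copy counts.

    family_rates maps CAZy family -> expected copy number (validated family
    labels; nonnegative rates). Returns (profiles, truth) with the true
    candidate flag and score per genome computed by an independent rule
    restatement.
    """
    for fam, rate in family_rates.items():
        normalize_family(fam)  # raises on unknown label shape
        if rate < 0:
            raise ValueError(f"negative rate for family {fam}")
    rng = np.random.default_rng(seed)
    fams = sorted(family_rates)
    rates = np.array([family_rates[f] for f in fams], dtype=float)
    profiles, rows = [], []
    for i in range(n_genomes):
        copies = rng.poisson(rates)
        counts = {f: int(c) for f, c in zip(fams, copies) if c > 0}
        profiles.append(CAZymeProfile(f"genome_{i:04d}", counts))
        score = _score_rule_oracle(counts)
        rows.append({"genome_id": f"genome_{i:04d}",
                     "true_candidate": score >= 1, "true_score": score})
    truth = pd.DataFrame(rows, columns=["genome_id", "true_candidate",
                                        "true_score"])
    return profiles, truth


# ---------------------------------------------------------------------------
# Oxygen-gradient assay simulation
# ---------------------------------------------------------------------------

def gen_assay_data(n_strains: int = 6,
                   o2_levels: Sequence[float] = (0.0, 2.0, 4.0, 6.0, 21.0),
                   effect_profile: Mapping[float, float] | Callable[[float], float] | None = None,
                   noise_sd: float = 0.05,
                   strain_sd: float = 0.1,
                   baseline: float = 0.2,
                   seed: int = 0) -> pd.DataFrame:
    """Generate per-strain, per-O2-level assay measurements (paired design).

    value = baseline + strain effect + effect_profile(o2) + N(0, noise_sd).
    The default effect profile is a step increase at 4% O2 followed by a
    graded gain toward 21%, emulating oxygen-dependent activity.
    """
    levels = list(o2_levels)
    if levels != sorted(levels):
        raise ValueError("o2_levels must be sorted ascending")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if effect_profile is None:
        effect_profile = lambda o2: 0.0 if o2 < 4 else 0.3 + 0.01 * (o2 - 4)  # noqa: E731
    effect = (effect_profile if callable(effect_profile)
              else lambda o2, _m=dict(effect_profile): _m[o2])
    rng = np.random.default_rng(seed)
    strain_eff = rng.normal(0.0, strain_sd, size=n_strains)
    rows = []
    for i in range(n_strains):
        for o2 in levels:
            val = (baseline + strain_eff[i] + effect(o2)
                   + rng.normal(0.0, noise_sd))
            rows.append({"strain_id": f"strain_{i + 1}", "o2_level": float(o2),
                         "replicate": 1, "value": float(val)})
    return pd.DataFrame(rows)
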