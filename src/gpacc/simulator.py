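"""Forward-in-time simulation of a closed breeding program.

The simulator produces the validation populations for the deterministic
accuracy models: a neutral historical phase generates drift-recombination
linkage disequilibrium and an allele-frequency spectrum in a finite random
mating population; loci passing a minor-allele-frequency filter are split
into markers and QTL; and discrete breeding generations with a hierarchical
sire-dam mating design follow, with parents picked at random or by GBLUP
GEBV computed before the candidates are phenotyped.

Genomes are sets of ``k`` chromosomes of length ``L`` Morgan with bi-allelic
loci.  Meiosis draws a Poisson(``L``) number of crossovers per chromosome
(no interference), uniform crossover positions, an independent random start
phase per chromosome, and recurrent mutation at a fixed per-locus rate.

True breeding values are the QTL-dosage weighted sums of normal QTL effects,
centered and scaled so that generation 0 has mean 0 and standard deviation
1; phenotypes add a normal environmental deviate sized to the requested
heritability on that scale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .relationships import Pedigree, build_G, write_dosages, write_pedigree
from .blup_engine import solve_blup

__all__ = [
    "GenomeSpec",
    "SimConfig",
    "FounderPool",
    "LociAssignment",
    "SimDataset",
    "simulate_historical",
    "assign_loci",
    "simulate_breeding",
    "run_simulation",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Genome layout: ``k`` chromosomes of ``L`` Morgan with ``n_loci`` loci."""

    k: int = 9
    L: float = 1.5
    n_loci: int = 40_000
    mutation_rate: float = 1e-8

    def __post_init__(self) -> None:
        if self.k < 1 or self.L <= 0 or self.n_loci < self.k:
            raise ValueError("invalid genome specification")
        if self.mutation_rate < 0:
            raise ValueError("mutation rate must be >= 0")

    @property
    def map_length(self) -> float:
        return self.k * self.L


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a simulated breeding program.

    Defaults mirror the base design used throughout: a 2000-generation
    historical phase of 250 males and 250 females, ~20k segregating loci of
    which 1000 are QTL, and 10 breeding generations of 10 sires x 120 dams
    with 12 progeny per dam (1440 genotyped and phenotyped individuals per
    generation).
    """

    genome: GenomeSpec = field(default_factory=GenomeSpec)
    n_hist_generations: int = 2000
    hist_ne: int = 500
    maf_min: float = 0.1
    n_qtl: int = 1000
    n_markers_target: Optional[int] = None
    h2: float = 0.4
    n_sires: int = 10
    n_dams: int = 120
    progeny_per_dam: int = 12
    n_generations: int = 10
    selection: Literal["random", "gebv"] = "random"
    g_method: Literal[1, 2] = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.h2 < 1.0):
            raise ValueError(f"h2 must be in (0, 1), got {self.h2}")
        if self.n_qtl % self.genome.k != 0:
            raise ValueError(
                f"n_qtl ({self.n_qtl}) must be divisible by the number of "
                f"chromosomes ({self.genome.k}) for equal per-chromosome counts"
            )
        for name in (
            "n_hist_generations",
            "hist_ne",
            "n_sires",
            "n_dams",
            "progeny_per_dam",
            "n_generations",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.selection not in ("random", "gebv"):
            raise ValueError(f"unknown selection mode {self.selection!r}")

    @property
    def n_per_generation(self) -> int:
        return self.n_dams * self.progeny_per_dam


@dataclass
class FounderPool:
    """Diploid haplotypes of the last historical generation."""

    haplotypes: np.ndarray  # (n, 2, n_loci) uint8
    positions: np.ndarray  # global map position (Morgan) per locus
    chrom: np.ndarray  # chromosome index per locus
    genome: GenomeSpec

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))


@dataclass
class LociAssignment:
    """Disjoint marker and QTL index sets with raw (unscaled) QTL effects."""

    marker_idx: np.ndarray
    qtl_idx: np.ndarray
    qtl_effects: np.ndarray

    def __post_init__(self) -> None:
        if np.intersect1d(self.marker_idx, self.qtl_idx).size:
            raise ValueError("marker and QTL sets overlap")


@dataclass
class SimDataset:
    """All tables produced by one simulated breeding program.

    Individuals are numbered 1..n in birth order; generation-0 individuals
    are pedigree founders (parents unknown).  ``markers`` holds 0/1/2 dosages
    row-aligned with ``pedigree``; ``tbv`` is on the generation-0 genetic-SD
    scale.
    """

    config: SimConfig
    pedigree: pd.DataFrame  # id, sire, dam, generation, sex
    markers: np.ndarray  # (n_total, n_markers) uint8
    tbv: np.ndarray
    phenotype: np.ndarray
    selected_parents: dict = field(default_factory=dict)
    marker_positions: Optional[np.ndarray] = None

    def ids_of(self, generations: Sequence[int]) -> np.ndarray:
        mask = self.pedigree["generation"].isin(list(generations))
        return self.pedigree.loc[mask, "id"].to_numpy()

    def rows_of(self, ids: np.ndarray) -> np.ndarray:
        # ids are 1-based birth-order, rows are ids - 1
        return np.asarray(ids, dtype=int) - 1

    def phenotype_table(self, ids: np.ndarray) -> pd.DataFrame:
        rows = self.rows_of(ids)
        return pd.DataFrame(
            {
                "id": ids,
                "value": self.phenotype[rows],
                "generation": self.pedigree["generation"].to_numpy()[rows],
            }
        )

    def with_phenotypes(self, h2: float, seed: int) -> "SimDataset":
        """Same genomes and pedigree with phenotypes redrawn at heritability h2.

        Only meaningful under random selection, where phenotypes do not feed
        back into the mating structure.
        """
        if self.config.selection != "random":
            raise ValueError(
                "phenotypes cannot be redrawn under GEBV selection: they "
                "determined the realized matings"
            )
        rng = np.random.default_rng(seed)
        sigma_e = np.sqrt((1.0 - h2) / h2)
        phen = self.tbv + rng.normal(0.0, sigma_e, size=len(self.tbv))
        cfg = dataclasses.replace(self.config, h2=h2)
        return SimDataset(
            config=cfg,
            pedigree=self.pedigree,
            markers=self.markers,
            tbv=self.tbv,
            phenotype=phen,
            selected_parents=self.selected_parents,
            marker_positions=self.marker_positions,
        )

    def write(self, outdir) -> None:
        """Write pedigree, genotypes, phenotypes, TBV and a manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_pedigree(Pedigree(self.pedigree[["id", "sire", "dam", "generation"]]),
                       outdir / "pedigree.csv")
        write_dosages(outdir / "genotypes.tsv", self.markers,
                      self.pedigree["id"].to_numpy())
        self.phenotype_table(self.pedigree["id"].to_numpy()).to_csv(
            outdir / "phenotypes.csv", index=False
        )
        pd.DataFrame(
            {"id": self.pedigree["id"], "tbv": self.tbv}
        ).to_csv(outdir / "tbv.tsv", sep="\t", index=False)
        manifest = dataclasses.asdict(self.config)
        manifest["genome"] = dataclasses.asdict(self.config.genome)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def _genome_positions(genome: GenomeSpec, rng: np.random.Generator):
    """Uniform locus positions; returns (global positions, chrom index)."""
    per = np.full(genome.k, genome.n_loci // genome.k)
    per[: genome.n_loci % genome.k] += 1
    pos_list, chrom_list = [], []
    for c in range(genome.k):
        p = np.sort(rng.uniform(0.0, genome.L, size=per[c]))
        pos_list.append(p + c * genome.L)
        chrom_list.append(np.full(per[c], c))
    return np.concatenate(pos_list), np.concatenate(chrom_list)


class _Meiosis:
    """Precomputed genome layout for fast repeated gamete formation."""

    def __init__(self, positions: np.ndarray, chrom: np.ndarray, genome: GenomeSpec):
        self.positions = positions
        self.chrom = chrom
        self.k = genome.k
        self.L = genome.L
        self.chrom_start_pos = np.arange(genome.k) * genome.L

    def gamete(self, haps: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """One recombinant gamete from a (2, n_loci) parent."""
        n_x = rng.poisson(self.L, size=self.k)
        total = int(n_x.sum())
        if total:
            offsets = np.repeat(self.chrom_start_pos, n_x)
            bp = np.sort(offsets + rng.uniform(0.0, self.L, size=total))
            idx = np.searchsorted(bp, self.positions)
            base = np.searchsorted(bp, self.chrom_start_pos)
            within = idx - base[self.chrom]
        else:
            within = np.zeros(len(self.positions), dtype=int)
        start = rng.integers(0, 2, size=self.k)
        phase = (start[self.chrom] + within) % 2
        return haps[phase, np.arange(len(self.positions))]


def _mutate(haps: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """Recurrent bi-allelic mutation: allele flips in place at the given rate."""
    if rate <= 0:
        return
    n_flip = rng.binomial(haps.size, rate)
    if n_flip:
        flat = rng.integers(0, haps.size, size=n_flip)
        haps.reshape(-1)[flat] ^= 1


# ---------------------------------------------------------------------------
# historical phase
# ---------------------------------------------------------------------------


def simulate_historical(
    genome: GenomeSpec,
    ne: int = 500,
    n_generations: int = 2000,
    seed: int = 0,
) -> FounderPool:
    """Neutral random-mating history generating LD and a frequency spectrum.

    ``ne`` diploids (half used as males, half as females each generation)
    start from Bernoulli(0.5) haplotypes and drift for ``n_generations``
    generations of random mating with recombination and recurrent mutation.
    """
    if ne < 2 or n_generations < 1:
        raise ValueError("ne must be >= 2 and n_generations >= 1")
    rng = np.random.default_rng(seed)
    positions, chrom = _genome_positions(genome, rng)
    meiosis = _Meiosis(positions, chrom, genome)
    haps = rng.integers(0, 2, size=(ne, 2, genome.n_loci), dtype=np.uint8)
    n_males = ne // 2
    for _ in range(n_generations):
        sires = rng.integers(0, n_males, size=ne)
        dams = rng.integers(n_males, ne, size=ne)
        nxt = np.empty_like(haps)
        for i in range(ne):
            nxt[i, 0] = meiosis.gamete(haps[sires[i]], rng)
            nxt[i, 1] = meiosis.gamete(haps[dams[i]], rng)
        _mutate(nxt, genome.mutation_rate, rng)
        haps = nxt
    freq = haps.mean(axis=(0, 1))
    if not ((freq > 0) & (freq < 1)).any():
        raise ValueError(
            "all loci fixed after the historical phase; simulate more loci "
            "or fewer generations relative to ne"
        )
    return FounderPool(haps, positions, chrom, genome)


# ---------------------------------------------------------------------------
# marker / QTL assignment
# ---------------------------------------------------------------------------


def assign_loci(
    pool: FounderPool,
    maf_min: float = 0.1,
    n_qtl: int = 1000,
    n_markers: Optional[int] = None,
    seed: int = 0,
) -> LociAssignment:
    """Split loci segregating above ``maf_min`` into QTL and marker panels.

    QTL are drawn at random with equal numbers per chromosome; the remaining
    qualifying loci become the marker panel (optionally thinned to
    ``n_markers``).  QTL effects are independent standard normals; the
    generation-0 scaling to unit genetic variance happens in
    :func:`simulate_breeding`.
    """
    genome = pool.genome
    if n_qtl % genome.k != 0:
        raise ValueError("n_qtl must be divisible by the number of chromosomes")
    rng = np.random.default_rng(seed)
    freq = pool.allele_frequencies()
    maf = np.minimum(freq, 1.0 - freq)
    qualify = maf > maf_min
    per_chrom = n_qtl // genome.k
    qtl_parts = []
    for c in range(genome.k):
        cand = np.flatnonzero(qualify & (pool.chrom == c))
        if len(cand) < per_chrom:
            raise ValueError(
                f"chromosome {c} has only {len(cand)} loci above MAF "
                f"{maf_min}, need {per_chrom} QTL"
            )
        qtl_parts.append(rng.choice(cand, size=per_chrom, replace=False))
    qtl_idx = np.sort(np.concatenate(qtl_parts))
    marker_idx = np.setdiff1d(np.flatnonzero(qualify), qtl_idx)
    if len(marker_idx) < 2:
        raise ValueError("insufficient qualifying loci to form a marker panel")
    if n_markers is not None:
        if n_markers > len(marker_idx):
            raise ValueError(
                f"requested {n_markers} markers but only {len(marker_idx)} "
                "qualifying loci remain"
            )
        marker_idx = np.sort(rng.choice(marker_idx, size=n_markers, replace=False))
    effects = rng.normal(size=n_qtl)
    return LociAssignment(marker_idx, qtl_idx, effects)


# ---------------------------------------------------------------------------
# breeding phase
# ---------------------------------------------------------------------------


def _litter_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Half male / half female per litter; an odd remainder is a coin flip."""
    half = n // 2
    sexes = np.array([0] * half + [1] * half, dtype=np.uint8)
    if n % 2:
        sexes = np.append(sexes, rng.integers(0, 2))
    return rng.permutation(sexes)


def _select_parents(
    candidates: pd.DataFrame,
    scores: Optional[np.ndarray],
    n_sires: int,
    n_dams: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    males = candidates.loc[candidates["sex"] == 0, "id"].to_numpy()
    females = candidates.loc[candidates["sex"] == 1, "id"].to_numpy()
    if len(males) < n_sires or len(females) < n_dams:
        raise ValueError(
            f"need {n_sires} sires and {n_dams} dams but only {len(males)} "
            f"males and {len(females)} females are available"
        )
    if scores is None:
        return rng.choice(males, n_sires, replace=False), rng.choice(
            females, n_dams, replace=False
        )
    score = pd.Series(scores, index=candidates["id"].to_numpy())
    sires = males[np.argsort(-score[males].to_numpy())][:n_sires]
    dams = females[np.argsort(-score[females].to_numpy())][:n_dams]
    return sires, dams


def simulate_breeding(
    cfg: SimConfig,
    pool: FounderPool,
    loci: Optional[LociAssignment] = None,
) -> SimDataset:
    """Run the breeding generations of the program described by ``cfg``.

    Generation 0 is bred by random mating of the founder pool and forms the
    pedigree base (parents unknown).  Each later generation is produced by a
    hierarchical mating of ``n_sires`` sires over ``n_dams`` dams (dams
    nested within sires, assignments random each generation), selected from
    the previous generation either at random or on GBLUP GEBV computed from
    all earlier phenotyped generations — i.e. before the candidates' own
    phenotypes exist.
    """
    rng = np.random.default_rng(cfg.seed)
    if loci is None:
        loci = assign_loci(
            pool,
            maf_min=cfg.maf_min,
            n_qtl=cfg.n_qtl,
            n_markers=cfg.n_markers_target,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    keep = np.union1d(loci.marker_idx, loci.qtl_idx)
    positions = pool.positions[keep]
    chrom = pool.chrom[keep]
    meiosis = _Meiosis(positions, chrom, pool.genome)
    marker_cols = np.searchsorted(keep, loci.marker_idx)
    qtl_cols = np.searchsorted(keep, loci.qtl_idx)

    n_per_gen = cfg.n_per_generation
    n_total = n_per_gen * (cfg.n_generations + 1)
    markers = np.empty((n_total, len(marker_cols)), dtype=np.uint8)
    tbv_raw = np.empty(n_total)
    ped_rows: List[tuple] = []
    selected: dict = {}

    pool_haps = pool.haplotypes[:, :, keep]
    pool_males = np.arange(pool.n // 2)
    pool_females = np.arange(pool.n // 2, pool.n)

    def make_offspring(row, sire_hap, dam_hap):
        child = np.empty((2, len(keep)), dtype=np.uint8)
        child[0] = meiosis.gamete(sire_hap, rng)
        child[1] = meiosis.gamete(dam_hap, rng)
        _mutate(child, pool.genome.mutation_rate, rng)
        markers[row] = child[:, marker_cols].sum(axis=0)
        tbv_raw[row] = child[:, qtl_cols].sum(axis=0) @ loci.qtl_effects
        return child

    # generation 0: random pool matings; individuals are pedigree founders
    gen_haps = np.empty((n_per_gen, 2, len(keep)), dtype=np.uint8)
    sexes = _litter_sexes(n_per_gen, rng)
    for i in range(n_per_gen):
        s = rng.choice(pool_males)
        d = rng.choice(pool_females)
        gen_haps[i] = make_offspring(i, pool_haps[s], pool_haps[d])
        ped_rows.append((i + 1, 0, 0, 0, sexes[i]))

    # scale TBV to mean 0 / sd 1 in generation 0 and attach phenotypes
    mu0 = tbv_raw[:n_per_gen].mean()
    sd0 = tbv_raw[:n_per_gen].std()
    if sd0 == 0:
        raise ValueError("generation 0 has zero genetic variance")
    sigma_e = np.sqrt((1.0 - cfg.h2) / cfg.h2)
    phen_noise = rng.normal(0.0, sigma_e, size=n_total)

    ped = None
    for gen in range(1, cfg.n_generations + 1):
        ped = pd.DataFrame(
            ped_rows, columns=["id", "sire", "dam", "generation", "sex"]
        )
        candidates = ped[ped["generation"] == gen - 1]
        scores = None
        if cfg.selection == "gebv" and gen >= 2:
            scores = _gebv_scores(
                cfg, ped, markers, tbv_raw, phen_noise, mu0, sd0, gen - 1
            )
        sires, dams = _select_parents(
            candidates, scores, cfg.n_sires, cfg.n_dams, rng
        )
        selected[gen] = {"sires": sires.tolist(), "dams": dams.tolist()}
        # hierarchical nesting: dams split evenly among sires
        dam_order = rng.permutation(dams)
        sire_of_dam = np.repeat(sires, int(np.ceil(len(dams) / len(sires))))[
            : len(dams)
        ]
        new_haps = np.empty_like(gen_haps)
        row = gen * n_per_gen
        for dam, sire in zip(dam_order, sire_of_dam):
            sexes = _litter_sexes(cfg.progeny_per_dam, rng)
            for j in range(cfg.progeny_per_dam):
                i_local = row - gen * n_per_gen
                new_haps[i_local] = make_offspring(
                    row,
                    gen_haps[int(sire) - 1 - (gen - 1) * n_per_gen],
                    gen_haps[int(dam) - 1 - (gen - 1) * n_per_gen],
                )
                ped_rows.append((row + 1, int(sire), int(dam), gen, sexes[j]))
                row += 1
        gen_haps = new_haps

    pedigree = pd.DataFrame(
        ped_rows, columns=["id", "sire", "dam", "generation", "sex"]
    )
    tbv = (tbv_raw - mu0) / sd0
    phen = tbv + phen_noise
    return SimDataset(
        config=cfg,
        pedigree=pedigree,
        markers=markers,
        tbv=tbv,
        phenotype=phen,
        selected_parents=selected,
        marker_positions=positions[marker_cols],
    )


def _gebv_scores(cfg, ped, markers, tbv_raw, phen_noise, mu0, sd0, cand_gen):
    """GBLUP GEBV of generation ``cand_gen`` from generations 0..cand_gen-1."""
    ref_mask = ped["generation"] < cand_gen
    cand_mask = ped["generation"] == cand_gen
    ids = ped.loc[ref_mask | cand_mask, "id"].to_numpy()
    rows = ids - 1
    G = build_G(markers[rows].astype(float), ids, method=cfg.g_method)
    ref_ids = ped.loc[ref_mask, "id"].to_numpy()
    tbv = (tbv_raw - mu0) / sd0
    phen = pd.DataFrame(
        {"id": ref_ids, "value": tbv[ref_ids - 1] + phen_noise[ref_ids - 1]}
    )
    cand_ids = ped.loc[cand_mask, "id"].to_numpy()
    fit = solve_blup(G, phen, cfg.h2, kind="G", evaluate_ids=cand_ids)
    return fit["ebv"].to_numpy()


def run_simulation(cfg: SimConfig) -> SimDataset:
    """History + locus assignment + breeding in one call, seeded from ``cfg``."""
    pool = simulate_historical(
        cfg.genome, ne=cfg.hist_ne, n_generations=cfg.n_hist_generations,
        seed=cfg.seed,
    )
    return simulate_breeding(cfg, pool)
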