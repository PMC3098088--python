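"""Forward-in-time breeding-population simulator (QTLMAS XII style design).

The default design: six 100 cM chromosomes carrying 1000 biallelic markers
each at 0.1 cM spacing; 48 additive biallelic QTL with gamma-distributed
allele-substitution effects and random sign, placed at inter-marker
midpoints on chromosomes 1-5 (the sixth chromosome is left empty of QTL);
founder allele frequencies 1/2 at every locus.  LD builds up over 50
generations of random mating at constant size (50 males + 50 females),
after which 15 males and 150 females start six generations of hierarchical
mating (each sire mated to 10 dams, 10 progeny per dam = 1500 per
generation).  The training set is the 165 initial parents plus the first
three hierarchical generations (4665 individuals, genotypes + phenotypes);
the validation set is 400 random progeny from each of the last three
generations (1200 individuals, genotypes and true breeding values only).

Meiosis uses the Haldane map function (no interference, no mutation):
recombination between adjacent loci at distance d cM occurs with
probability ``(1 - exp(-2d/100)) / 2``, and chromosomes assort
independently.  The residual variance is calibrated after the training
population exists so that the in-sample heritability equals the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import RawGenotypes, TraitData

__all__ = [
    "SimParams",
    "QTLTruth",
    "SimDataset",
    "haldane_r",
    "sample_gamete",
    "simulate_qtlmas",
    "qtl_variance_shares",
]


def haldane_r(d_cm) -> np.ndarray:
    """Haldane recombination fraction for a distance in cM:
    r = (1 - exp(-2 d / 100)) / 2."""
    d = np.asarray(d_cm, dtype=float)
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


@dataclass
class SimParams:
    n_chrom: int = 6
    markers_per_chrom: int = 1000
    spacing_cm: float = 0.1
    n_qtl: int = 48
    qtl_gamma_shape: float = 0.4
    # default: every chromosome except the last stays QTL-free territory
    # (None resolves to (1, ..., n_chrom-1); (1,...,5) under the defaults)
    qtl_chromosomes: tuple | None = None
    h2: float = 0.3
    target_sigma_y2: float | None = 4.42
    n_random_generations: int = 50
    random_males: int = 50
    random_females: int = 50
    n_sires: int = 15
    n_dams: int = 150
    progeny_per_dam: int = 10
    n_selected_generations: int = 6
    n_training_selected_generations: int = 3
    validation_sample_per_generation: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_chrom",
            "markers_per_chrom",
            "n_qtl",
            "n_random_generations",
            "random_males",
            "random_females",
            "n_sires",
            "n_dams",
            "progeny_per_dam",
            "n_selected_generations",
            "validation_sample_per_generation",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError("h2 must be in (0, 1]")
        if self.spacing_cm <= 0:
            raise ValueError("spacing_cm must be positive")
        if self.qtl_chromosomes is None:
            self.qtl_chromosomes = tuple(range(1, max(self.n_chrom, 2)))
        if self.n_dams % self.n_sires != 0:
            raise ValueError("n_dams must be a multiple of n_sires")
        n_prog = self.n_dams * self.progeny_per_dam
        if self.validation_sample_per_generation > n_prog:
            raise ValueError("validation sample exceeds generation size")
        if self.n_training_selected_generations >= self.n_selected_generations:
            raise ValueError("training generations must leave validation generations")
        if max(self.qtl_chromosomes) > self.n_chrom:
            raise ValueError("qtl_chromosomes outside the simulated genome")
        if self.n_qtl > (self.markers_per_chrom - 1) * len(self.qtl_chromosomes):
            raise ValueError("more QTL than inter-marker midpoints available")

    @property
    def n_markers(self) -> int:
        return self.n_chrom * self.markers_per_chrom

    @property
    def progeny_per_generation(self) -> int:
        return self.n_dams * self.progeny_per_dam


@dataclass
class QTLTruth:
    """Per-QTL truth: map position, allele-substitution effect (trait
    units) and the percentage of total genetic variance explained in the
    training set (locus-wise shares renormalized to sum to 100)."""

    chrom: np.ndarray
    pos_cm: np.ndarray
    effect: np.ndarray
    variance_share_pct: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "qtl_id": [f"qtl{i + 1}" for i in range(len(self.effect))],
                "chromosome": self.chrom,
                "position_cM": self.pos_cm,
                "effect": self.effect,
                "variance_share_pct": self.variance_share_pct,
            }
        )


@dataclass
class SimDataset:
    training: RawGenotypes
    training_trait: TraitData
    training_tbv: np.ndarray
    validation: RawGenotypes
    validation_tbv: np.ndarray
    validation_generation: np.ndarray
    truth: QTLTruth
    realized_sigma_y2: float
    realized_h2: float
    params: SimParams = field(repr=False, default=None)
    training_qtl_codes: np.ndarray = field(repr=False, default=None)


def _interval_recomb(chrom: np.ndarray, pos_cm: np.ndarray) -> np.ndarray:
    """Recombination probability for each adjacent locus pair; 0.5 across
    chromosome boundaries (independent assortment)."""
    r = haldane_r(np.diff(pos_cm))
    r[np.diff(chrom) != 0] = 0.5
    return r


def _meiosis_batch(hap0: np.ndarray, hap1: np.ndarray, r: np.ndarray, rng) -> np.ndarray:
    """Sample one gamete per row from (k, L) parental haplotype pairs."""
    k, L = hap0.shape
    thresh = np.empty(L)
    thresh[0] = 0.5  # random starting haplotype per meiosis
    thresh[1:] = r
    switch = rng.random((k, L)) < thresh
    phase = np.cumsum(switch, axis=1) & 1
    return np.where(phase == 0, hap0, hap1).astype(np.uint8)


def sample_gamete(parent_haplotypes, chrom, pos_cm, rng) -> np.ndarray:
    """Sample a single gamete from a pair of binary haplotype vectors
    under the Haldane model (no interference)."""
    hap0, hap1 = parent_haplotypes
    hap0 = np.atleast_2d(np.asarray(hap0, dtype=np.uint8))
    hap1 = np.atleast_2d(np.asarray(hap1, dtype=np.uint8))
    r = _interval_recomb(np.asarray(chrom), np.asarray(pos_cm))
    return _meiosis_batch(hap0, hap1, r, rng)[0]


def _offspring(haps: np.ndarray, sires: np.ndarray, dams: np.ndarray, r, rng):
    """Diploid offspring (k, 2, L) from parent indices into ``haps``."""
    pat = _meiosis_batch(haps[sires, 0], haps[sires, 1], r, rng)
    mat = _meiosis_batch(haps[dams, 0], haps[dams, 1], r, rng)
    return np.stack([pat, mat], axis=1)


def simulate_qtlmas(params: SimParams | None = None) -> SimDataset:
    """Run the full forward simulation; bit-reproducible from ``seed``."""
    p = params or SimParams()
    rng = np.random.default_rng(p.seed)

    # --- genome: markers at regular spacing, QTL at inter-marker midpoints
    marker_chrom = np.repeat(np.arange(1, p.n_chrom + 1), p.markers_per_chrom)
    marker_pos = np.tile(
        p.spacing_cm * np.arange(p.markers_per_chrom), p.n_chrom
    ).astype(float)
    mid_chrom = []
    mid_pos = []
    for c in p.qtl_chromosomes:
        mid_chrom.append(np.full(p.markers_per_chrom - 1, c))
        mid_pos.append(p.spacing_cm * (np.arange(p.markers_per_chrom - 1) + 0.5))
    mid_chrom = np.concatenate(mid_chrom)
    mid_pos = np.concatenate(mid_pos)
    pick = np.sort(rng.choice(mid_chrom.size, size=p.n_qtl, replace=False))
    qtl_chrom = mid_chrom[pick]
    qtl_pos = mid_pos[pick]

    # interleave markers and QTL into one locus array ordered by (chrom, pos)
    all_chrom = np.concatenate([marker_chrom, qtl_chrom])
    all_pos = np.concatenate([marker_pos, qtl_pos])
    is_marker = np.concatenate(
        [np.ones(marker_chrom.size, bool), np.zeros(qtl_chrom.size, bool)]
    )
    order = np.lexsort((all_pos, all_chrom))
    all_chrom, all_pos, is_marker = all_chrom[order], all_pos[order], is_marker[order]
    L = all_chrom.size
    r = _interval_recomb(all_chrom, all_pos)
    qtl_cols = np.flatnonzero(~is_marker)
    marker_cols = np.flatnonzero(is_marker)

    # --- QTL effects: gamma magnitudes, random sign
    effects = rng.gamma(p.qtl_gamma_shape, 1.0, size=p.n_qtl)
    effects *= rng.choice((-1.0, 1.0), size=p.n_qtl)

    # --- founders and random-mating phase (equal allele frequencies 1/2)
    n_rand = p.random_males + p.random_females
    haps = (rng.random((n_rand, 2, L)) < 0.5).astype(np.uint8)
    for _ in range(p.n_random_generations):
        sires = rng.integers(0, p.random_males, size=n_rand)
        dams = p.random_males + rng.integers(0, p.random_females, size=n_rand)
        haps = _offspring(haps, sires, dams, r, rng)

    # --- initial hierarchical parents: 15 males + 150 females bred from the
    # last random generation
    n_par = p.n_sires + p.n_dams
    sires = rng.integers(0, p.random_males, size=n_par)
    dams = p.random_males + rng.integers(0, p.random_females, size=n_par)
    par_haps = _offspring(haps, sires, dams, r, rng)
    par_sex = np.concatenate(
        [np.zeros(p.n_sires, dtype=int), np.ones(p.n_dams, dtype=int)]
    )  # 0 = male

    generations: list[np.ndarray] = []  # diploid haplotypes per generation
    cur_haps, cur_sex = par_haps, par_sex
    for _ in range(p.n_selected_generations):
        males = np.flatnonzero(cur_sex == 0)
        females = np.flatnonzero(cur_sex == 1)
        if males.size < p.n_sires or females.size < p.n_dams:
            raise ValueError("not enough candidates of one sex for selection")
        sel_sires = rng.choice(males, size=p.n_sires, replace=False)
        sel_dams = rng.choice(females, size=p.n_dams, replace=False)
        # each sire mated to a random block of dams, 10 progeny per dam
        dam_order = rng.permutation(sel_dams)
        dams_per_sire = p.n_dams // p.n_sires
        sire_of_dam = np.repeat(sel_sires, dams_per_sire)
        off_sires = np.repeat(sire_of_dam, p.progeny_per_dam)
        off_dams = np.repeat(dam_order, p.progeny_per_dam)
        new_haps = _offspring(cur_haps, off_sires, off_dams, r, rng)
        new_sex = rng.integers(0, 2, size=new_haps.shape[0])
        generations.append(new_haps)
        cur_haps, cur_sex = new_haps, new_sex

    # --- assemble training (initial parents + first k generations) and
    # validation (random samples from the last generations)
    n_tr_gen = p.n_training_selected_generations
    train_blocks = [par_haps] + generations[:n_tr_gen]
    train_gen_labels = np.concatenate(
        [np.full(b.shape[0], i) for i, b in enumerate(train_blocks)]
    )
    train_haps = np.concatenate(train_blocks, axis=0)

    val_blocks = []
    val_labels = []
    for i, g in enumerate(generations[n_tr_gen:], start=n_tr_gen + 1):
        idx = rng.choice(g.shape[0], size=p.validation_sample_per_generation, replace=False)
        val_blocks.append(g[np.sort(idx)])
        val_labels.append(np.full(p.validation_sample_per_generation, i))
    val_haps = np.concatenate(val_blocks, axis=0)
    val_labels = np.concatenate(val_labels)

    def codes_of(h: np.ndarray) -> np.ndarray:
        return h.sum(axis=1, dtype=np.int8)

    train_codes = codes_of(train_haps)
    val_codes = codes_of(val_haps)

    train_qtl = train_codes[:, qtl_cols].astype(float)
    val_qtl = val_codes[:, qtl_cols].astype(float)
    tbv_train = train_qtl @ effects
    tbv_val = val_qtl @ effects

    # effect scale calibrated in-sample to the target phenotypic variance,
    # residual variance to the target heritability
    var_g = float(np.var(tbv_train))
    if var_g <= 0.0:
        raise ValueError("no genetic variance realized; increase n_qtl or seed")
    if p.target_sigma_y2 is not None:
        scale = np.sqrt(p.h2 * p.target_sigma_y2 / var_g)
        effects *= scale
        tbv_train *= scale
        tbv_val *= scale
        var_g = float(np.var(tbv_train))
    sigma_e2 = var_g * (1.0 - p.h2) / p.h2
    y = tbv_train + rng.normal(0.0, np.sqrt(sigma_e2), size=tbv_train.size)
    var_y = float(np.var(y))

    snp_ids = [f"snp{j + 1}" for j in range(marker_cols.size)]
    train_ids = [
        f"G{g}_{i + 1}"
        for g, i in zip(
            train_gen_labels,
            np.concatenate([np.arange(b.shape[0]) for b in train_blocks]),
        )
    ]
    val_ids = [f"G{g}_{i + 1}" for i, g in enumerate(val_labels)]

    training = RawGenotypes(
        codes=train_codes[:, marker_cols],
        individual_ids=train_ids,
        snp_ids=snp_ids,
        chrom=all_chrom[marker_cols],
        pos_cm=all_pos[marker_cols],
    )
    validation = RawGenotypes(
        codes=val_codes[:, marker_cols],
        individual_ids=val_ids,
        snp_ids=snp_ids,
        chrom=all_chrom[marker_cols],
        pos_cm=all_pos[marker_cols],
    )

    # locus-wise variance decomposition (ignores LD between QTL)
    per_qtl_var = np.var(train_qtl * effects, axis=0)
    shares = 100.0 * per_qtl_var / per_qtl_var.sum()
    truth = QTLTruth(
        chrom=qtl_chrom,
        pos_cm=qtl_pos,
        effect=effects,
        variance_share_pct=shares,
    )

    return SimDataset(
        training=training,
        training_trait=TraitData(
            y=y, individual_ids=train_ids, generation=train_gen_labels
        ),
        training_tbv=tbv_train,
        validation=validation,
        validation_tbv=tbv_val,
        validation_generation=val_labels,
        truth=truth,
        realized_sigma_y2=var_y,
        realized_h2=var_g / var_y,
        params=p,
        training_qtl_codes=train_qtl,
    )


def qtl_variance_shares(
    dataset: SimDataset, thresholds=(0.1, 1.0, 5.0, 10.0)
) -> tuple[np.ndarray, dict[float, int]]:
    """Per-QTL percentage of total genetic variance in the training set
    (locus-wise), plus counts of QTL exceeding each threshold percentage."""
    shares = dataset.truth.variance_share_pct
    counts = {t: int(np.sum(shares > t)) for t in thresholds}
    return shares, counts
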