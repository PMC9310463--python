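"""Synthetic screens and droplet datasets with known ground truth.

The screen generator emulates the layout of a genome-wide two-dimensional
screen: negative controls and non-expressors are pure measurement noise,
regulators additively shift a fixed fraction of readouts, positive controls
replicate one strong regulator's profile, and (optionally) off-target events
are planted by giving one "single siRNA" of a non-expressor pool both a copy
of a regulator's response and a >= 11-nt complementary island against that
regulator's transcript.  The droplet generator emulates the four canonical
droplet classes — high-quality cells, empty (ambient-only) droplets, broken
cells with selective cytoplasmic leakage (elevated %mt), and stripped nuclei
(low %mt and low ribosomal content).

Effects are additive on the measurement scale before Z-scoring, so the Z-score
of a perturbed readout is approximately ``effect_size / noise_sd`` (with the
default ``noise_sd = 1`` the two coincide).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .io_preprocess import ScreenMatrix
from .offtarget import SirnaLibrary

__all__ = [
    "ScreenSimConfig",
    "SimulatedScreen",
    "simulate_screen",
    "DropletSimConfig",
    "SimulatedDroplets",
    "simulate_droplets",
]

_RNA = np.array(list("ACGU"))
_DNA = np.array(list("ACGT"))
_RC_DNA_TO_RNA = str.maketrans("ACGT", "UGCA")


@dataclass
class ScreenSimConfig:
    """Study conditions for the synthetic two-dimensional screen.

    Defaults describe a well-powered genome-scale screen: 2,000 screened rows
    (200 true regulators among 1,580 inert genes and 200 non-expressors) over
    300 readouts, regulators perturbing 30% of readouts at 6 noise-SD units,
    with 10 controls per class.
    """

    n_readouts: int = 300
    n_regulators: int = 200
    n_inert: int = 1580
    n_non_expressors: int = 200
    n_pos_controls: int = 10
    n_neg_controls: int = 10
    effect_fraction: float = 0.3
    effect_size: float = 6.0
    direction_bias: float = 0.5
    noise_sd: float = 1.0
    n_offtarget_plants: int = 0
    offtarget_pool_scale: float = 0.8
    guide_length: int = 21
    guides_per_pool: int = 4
    transcript_length: int = 500
    plant_match_length: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_readouts,
            self.n_regulators,
            self.n_inert,
            self.n_non_expressors,
            self.n_pos_controls,
            self.n_neg_controls,
            self.n_offtarget_plants,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not (0.0 < self.effect_fraction <= 1.0):
            raise ValueError("effect_fraction must be in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not (0.0 <= self.direction_bias <= 1.0):
            raise ValueError("direction_bias must be in [0, 1]")
        if self.n_offtarget_plants > min(self.n_non_expressors, max(self.n_regulators, 1)):
            raise ValueError("more off-target plants than available pools")


@dataclass
class SimulatedScreen:
    matrix: ScreenMatrix
    annotation: pd.Series
    truth: pd.DataFrame
    library: SirnaLibrary | None = None
    secondary: ScreenMatrix | None = None


def _random_seq(rng: np.random.Generator, length: int, alphabet=_DNA) -> str:
    return "".join(rng.choice(alphabet, size=length))


def simulate_screen(cfg: ScreenSimConfig) -> SimulatedScreen:
    """Generate a primary screen matrix, row annotation and ground truth.

    Deterministic given ``cfg.seed``.  When ``cfg.n_offtarget_plants > 0`` a
    guide/transcript library (regulators and non-expressor pools) and a
    secondary screen of individual siRNAs are generated as well.
    """
    rng = np.random.default_rng(cfg.seed)
    M = cfg.n_readouts

    groups = [
        ("REG", cfg.n_regulators, "sample"),
        ("GENE", cfg.n_inert, "sample"),
        ("NE", cfg.n_non_expressors, "non_expressor"),
        ("POS", cfg.n_pos_controls, "positive_control"),
        ("NEG", cfg.n_neg_controls, "negative_control"),
    ]
    row_ids, classes = [], []
    for prefix, count, cls in groups:
        row_ids += [f"{prefix}{i:04d}" for i in range(count)]
        classes += [cls] * count
    N = len(row_ids)

    col_ids = [f"readout{j:03d}" for j in range(M)]
    col_mean = rng.normal(0.0, 1.0, size=M)  # per-readout baseline, removed by Z-scoring
    values = col_mean + rng.normal(0.0, cfg.noise_sd, size=(N, M))

    n_affect = max(1, int(round(cfg.effect_fraction * M)))
    reg_readouts = np.zeros((cfg.n_regulators, M), dtype=bool)
    reg_signs = np.zeros((cfg.n_regulators, M), dtype=float)
    for r in range(cfg.n_regulators):
        cols = rng.choice(M, size=n_affect, replace=False)
        signs = np.where(rng.random(n_affect) < cfg.direction_bias, 1.0, -1.0)
        reg_readouts[r, cols] = True
        reg_signs[r, cols] = signs
        values[r, cols] += cfg.effect_size * signs

    # positive controls replicate the first regulator's profile with fresh noise
    pos_start = cfg.n_regulators + cfg.n_inert + cfg.n_non_expressors
    if cfg.n_pos_controls and cfg.n_regulators:
        for p in range(cfg.n_pos_controls):
            values[pos_start + p] = (
                col_mean
                + rng.normal(0.0, cfg.noise_sd, size=M)
                + cfg.effect_size * reg_signs[0]
            )

    truth = pd.DataFrame(
        {
            "row_id": row_ids,
            "class": classes,
            "is_regulator": [i < cfg.n_regulators for i in range(N)],
            "n_affected": [int(reg_readouts[i].sum()) if i < cfg.n_regulators else 0 for i in range(N)],
            "planted_offtarget": False,
            "offtarget_source": "",
            "planted_sirna": "",
        }
    ).set_index("row_id")

    library = None
    secondary = None
    if cfg.n_offtarget_plants > 0:
        ne_start = cfg.n_regulators + cfg.n_inert
        ne_ids = row_ids[ne_start : ne_start + cfg.n_non_expressors]
        reg_ids = row_ids[: cfg.n_regulators]
        lib_pools = {pid: pid for pid in reg_ids + ne_ids}
        transcripts = {
            pid: _random_seq(rng, cfg.transcript_length) for pid in lib_pools
        }
        guides: dict[str, tuple[str, str]] = {}
        for pid in lib_pools:
            for s in range(cfg.guides_per_pool):
                guides[f"{pid}_s{s + 1}"] = (
                    pid,
                    _random_seq(rng, cfg.guide_length, _RNA),
                )

        planted_pools = list(rng.choice(ne_ids, size=cfg.n_offtarget_plants, replace=False))
        source_regs = list(
            rng.choice(reg_ids, size=cfg.n_offtarget_plants, replace=False)
        )
        plant_rows = []
        for pool, src in zip(planted_pools, source_regs):
            i_pool = row_ids.index(pool)
            i_src = row_ids.index(src)
            # the pool's primary response is a diluted copy of the regulator's
            values[i_pool] = (
                col_mean
                + rng.normal(0.0, cfg.noise_sd, size=M)
                + cfg.offtarget_pool_scale * cfg.effect_size * reg_signs[i_src]
            )
            # one guide of the pool carries the complementary island
            sid = f"{pool}_s1"
            tpos = int(rng.integers(0, cfg.transcript_length - cfg.plant_match_length))
            island = transcripts[src][tpos : tpos + cfg.plant_match_length]
            island_rc_rna = island.translate(_RC_DNA_TO_RNA)[::-1]
            g = list(guides[sid][1])
            offset = 3
            g[offset : offset + cfg.plant_match_length] = island_rc_rna
            guides[sid] = (pool, "".join(g))
            plant_rows.append((pool, src, sid))
            truth.loc[pool, ["planted_offtarget", "offtarget_source", "planted_sirna"]] = (
                True,
                src,
                sid,
            )
        library = SirnaLibrary(pools=lib_pools, guides=guides, transcripts=transcripts)

        # secondary screen: individual siRNAs of every library pool
        sec_ids = list(guides)
        sec = col_mean + rng.normal(0.0, cfg.noise_sd, size=(len(sec_ids), M))
        planted_sids = {sid for _, _, sid in plant_rows}
        for si, sid in enumerate(sec_ids):
            pool = guides[sid][0]
            if sid in planted_sids:
                src = next(s for p, s, d in plant_rows if d == sid)
                sec[si] += cfg.effect_size * reg_signs[row_ids.index(src)]
            elif pool in reg_ids:
                # on-target singles reproduce the pool effect at variable potency
                sec[si] += rng.uniform(0.6, 1.0) * cfg.effect_size * reg_signs[row_ids.index(pool)]
        secondary = ScreenMatrix(pd.DataFrame(sec, index=sec_ids, columns=col_ids))

    matrix = ScreenMatrix(pd.DataFrame(values, index=row_ids, columns=col_ids))
    annotation = pd.Series(classes, index=pd.Index(row_ids, name="row_id"), name="class")
    return SimulatedScreen(
        matrix=matrix, annotation=annotation, truth=truth, library=library, secondary=secondary
    )


@dataclass
class DropletSimConfig:
    """Study conditions for the synthetic droplet dataset.

    Defaults produce 10,000 droplets: 4,000 high-quality cells, 4,000 empty
    droplets, 1,000 broken cells and 1,000 stripped nuclei over 2,000 genes.
    Broken cells are simulated mechanistically, by binomially thinning the
    cytoplasmic (non-mitochondrial) counts of a high-quality cell while
    keeping its mitochondrial counts — selective leakage raises %mt and
    shrinks depth much faster than it shrinks nFeature.
    """

    n_high_quality: int = 4000
    n_empty: int = 4000
    n_broken: int = 1000
    n_stripped_nuclei: int = 1000
    n_genes: int = 2000
    frac_mito_genes: float = 0.01
    frac_ribo_genes: float = 0.05
    hq_depth: float = 8000.0
    hq_depth_sigma: float = 0.35
    # intact-cell heterogeneity: (population share, depth factor, profile
    # log-normal sigma).  Larger sigma concentrates expression on fewer genes
    # (a low-complexity, high-count program, e.g. erythroid/plasma-like).
    cell_types: tuple = (
        (0.30, 1.0, 2.0),
        (0.25, 1.4, 2.0),
        (0.20, 0.6, 2.0),
        (0.25, 1.0, 3.0),
    )
    empty_depth: float = 80.0
    empty_depth_sigma: float = 0.5
    mito_expression_share: float = 0.08
    ribo_expression_share: float = 0.20
    broken_retention: tuple[float, float] = (0.1, 0.5)
    nucleus_scale: float = 0.3
    nucleus_mt_retention: float = 0.05
    nucleus_ribo_retention: float = 0.15
    overdispersion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_high_quality, self.n_empty, self.n_broken, self.n_stripped_nuclei) < 0:
            raise ValueError("class counts must be >= 0")
        if self.frac_mito_genes + self.frac_ribo_genes > 1.0:
            raise ValueError("gene-class fractions must sum to <= 1")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")


@dataclass
class SimulatedDroplets:
    counts: sparse.csr_matrix  # cells x genes
    obs: pd.DataFrame  # per-cell: barcode index, class label
    var: pd.DataFrame  # per-gene: symbol, mt, ribo

    def to_anndata(self):
        import anndata as ad

        return ad.AnnData(X=self.counts.copy(), obs=self.obs.copy(), var=self.var.copy())


def _nb_counts(rng, lam: np.ndarray, overdispersion: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) counts with mean ``lam``."""
    if overdispersion <= 0:
        return rng.poisson(lam)
    shape = 1.0 / overdispersion
    return rng.poisson(rng.gamma(shape, lam * overdispersion))


def simulate_droplets(cfg: DropletSimConfig) -> SimulatedDroplets:
    """Generate a droplet count matrix with per-cell class labels.

    Deterministic given ``cfg.seed``.  The ambient profile of empty droplets
    is the mean expression profile of high-quality cells (mimicking RNA from
    lysed cells); broken cells and stripped nuclei are derived from
    high-quality cells by class-specific thinning.
    """
    rng = np.random.default_rng(cfg.seed)
    G = cfg.n_genes
    n_mt = max(1, int(round(cfg.frac_mito_genes * G)))
    n_ribo = max(1, int(round(cfg.frac_ribo_genes * G)))

    symbols = (
        [f"MT-G{i}" for i in range(n_mt)]
        + [f"RPL{i}" if i % 2 == 0 else f"RPS{i}" for i in range(n_ribo)]
        + [f"GENE{i:04d}" for i in range(G - n_mt - n_ribo)]
    )
    mt_mask = np.zeros(G, dtype=bool)
    mt_mask[:n_mt] = True
    ribo_mask = np.zeros(G, dtype=bool)
    ribo_mask[n_mt : n_mt + n_ribo] = True

    # per-cell-type relative-expression profiles: log-normal weights with a
    # type-specific sigma, renormalised so the mitochondrial and ribosomal
    # blocks carry their configured shares in every type
    shares = np.array([t[0] for t in cfg.cell_types], dtype=float)
    shares = shares / shares.sum()
    other = ~(mt_mask | ribo_mask)
    mito_w = np.exp(rng.normal(0.0, 1.0, size=n_mt))
    ribo_w = np.exp(rng.normal(0.0, 1.0, size=n_ribo))
    profiles = []
    for _, _, psigma in cfg.cell_types:
        w = np.exp(rng.normal(0.0, psigma, size=G))
        p = np.zeros(G)
        for mask, share, blockw in (
            (mt_mask, cfg.mito_expression_share, mito_w),
            (ribo_mask, cfg.ribo_expression_share, ribo_w),
            (other, 1.0 - cfg.mito_expression_share - cfg.ribo_expression_share, w[other]),
        ):
            p[mask] = share * blockw / blockw.sum()
        profiles.append(p)
    profiles = np.array(profiles)
    depth_factors = np.array([t[1] for t in cfg.cell_types], dtype=float)
    ambient = shares @ profiles  # lysed-cell RNA pooled over types

    def _intact(n, depth_scale, od):
        types = rng.choice(len(shares), size=n, p=shares)
        d = rng.lognormal(np.log(cfg.hq_depth * depth_scale), cfg.hq_depth_sigma, size=n)
        lam = (d * depth_factors[types])[:, None] * profiles[types]
        return _nb_counts(rng, lam, od)

    hq = _intact(cfg.n_high_quality, 1.0, cfg.overdispersion)
    d_empty = rng.lognormal(np.log(cfg.empty_depth), cfg.empty_depth_sigma, size=cfg.n_empty)
    empty = rng.poisson(d_empty[:, None] * ambient[None, :])

    broken_base = _intact(cfg.n_broken, 1.0, cfg.overdispersion)
    q = rng.uniform(*cfg.broken_retention, size=cfg.n_broken)
    broken = broken_base.copy()
    broken[:, ~mt_mask] = rng.binomial(broken_base[:, ~mt_mask], q[:, None])

    nuc_base = _intact(cfg.n_stripped_nuclei, cfg.nucleus_scale, cfg.overdispersion)
    nuc = nuc_base.copy()
    nuc[:, mt_mask] = rng.binomial(nuc_base[:, mt_mask], cfg.nucleus_mt_retention)
    nuc[:, ribo_mask] = rng.binomial(nuc_base[:, ribo_mask], cfg.nucleus_ribo_retention)

    blocks = [
        (hq, "high_quality"),
        (empty, "empty"),
        (broken, "broken"),
        (nuc, "stripped_nucleus"),
    ]
    X = sparse.csr_matrix(np.vstack([b for b, _ in blocks]).astype(np.int64))
    labels = np.concatenate([[lab] * b.shape[0] for b, lab in blocks])
    barcodes = [f"CELL{i:05d}" for i in range(X.shape[0])]
    obs = pd.DataFrame({"droplet_class": labels}, index=pd.Index(barcodes, name="barcode"))
    var = pd.DataFrame(
        {"symbol": symbols, "mt": mt_mask, "ribo": ribo_mask},
        index=pd.Index(symbols, name="gene_id"),
    )
    return SimulatedDroplets(counts=X, obs=obs, var=var)
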