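"""siRNA off-target detection: sequence complementarity + response similarity.

A pooled siRNA reagent can silence an unintended transcript through partial
complementarity (microRNA-like off-targeting).  In a two-dimensional screen
the consequence is visible: the off-targeting pool reproduces the readout
profile of the gene it accidentally silences.  A pool is flagged when both
lines of evidence agree — (i) one of its guides carries at least ``min_len``
(default 11) nucleotides of contiguous Watson-Crick complementarity to another
hit gene's transcript, and (ii) that same guide (in the secondary screen of
individual siRNAs) or, lacking one, the pool itself correlates with that
gene's response at Pearson r >= ``r_min`` (default 0.6).  Wobble (G.U) pairs
are not counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SirnaLibrary",
    "Match",
    "response_similarity",
    "complementarity_scan",
    "reverse_complement",
    "attribute_to_single_sirna",
    "flag_offtargets",
]

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")
_VALID = set("ACGTU")


def _validate_seq(seq: str, name: str = "sequence") -> str:
    s = seq.upper()
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"{name} contains invalid characters: {sorted(bad)}")
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement, emitted in the DNA alphabet (U treated as T)."""
    return _validate_seq(seq).translate(_COMPLEMENT)[::-1]


@dataclass
class SirnaLibrary:
    """Guide library: pool -> gene, guides per pool, transcript per gene.

    ``guides`` maps sirna_id -> (pool_id, guide sequence, 19-23 nt typically,
    RNA or DNA alphabet); ``pools`` maps pool_id -> gene_id; ``transcripts``
    maps gene_id -> transcript sequence.
    """

    pools: dict[str, str] = field(default_factory=dict)
    guides: dict[str, tuple[str, str]] = field(default_factory=dict)
    transcripts: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, (pool, g) in self.guides.items():
            g = _validate_seq(g, f"guide {sid}")
            if len(g) < 11:
                raise ValueError(f"guide {sid} shorter than 11 nt")
            self.guides[sid] = (pool, g)
        self.transcripts = {
            g: _validate_seq(s, f"transcript {g}") for g, s in self.transcripts.items()
        }

    def guides_of_pool(self, pool_id: str) -> dict[str, str]:
        return {sid: g for sid, (p, g) in self.guides.items() if p == pool_id}

    def write_guides_tsv(self, path) -> None:
        rows = [(sid, p, g) for sid, (p, g) in self.guides.items()]
        pd.DataFrame(rows, columns=["sirna_id", "pool_id", "guide"]).to_csv(
            path, sep="\t", index=False
        )

    def write_transcripts_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        recs = [SeqRecord(Seq(s), id=g, description="") for g, s in self.transcripts.items()]
        seqio_write(recs, str(path), "fasta")

    @classmethod
    def read(cls, guides_tsv, transcripts_fasta, pools: dict[str, str] | None = None):
        from Bio import SeqIO

        gdf = pd.read_csv(guides_tsv, sep="\t")
        guides = {r.sirna_id: (r.pool_id, r.guide) for r in gdf.itertuples()}
        transcripts = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(transcripts_fasta), "fasta")
        }
        if pools is None:
            pools = {p: p for p, _ in guides.values()}
        return cls(pools=pools, guides=guides, transcripts=transcripts)


@dataclass
class Match:
    """A maximal contiguous complementary run on a transcript (1-based,
    inclusive coordinates)."""

    length: int
    t_start: int
    t_end: int
    g_start: int  # 1-based position on the reverse-complemented guide
    g_end: int


def response_similarity(zm, a: str, b: str, min_shared: int = 10) -> float:
    """Pearson correlation of two perturbations' Z-score rows over their
    mutually observed readouts."""
    za = zm.z.loc[a].to_numpy(float)
    zb = zm.z.loc[b].to_numpy(float)
    shared = np.isfinite(za) & np.isfinite(zb)
    if shared.sum() < min_shared:
        raise ValueError(f"fewer than {min_shared} shared readouts for {a} vs {b}")
    xa, xb = za[shared], zb[shared]
    if np.std(xa) == 0 or np.std(xb) == 0:
        raise ValueError("zero variance in a response row; correlation undefined")
    return float(stats.pearsonr(xa, xb)[0])


def complementarity_scan(guide: str, transcript: str, min_len: int = 11) -> list[Match]:
    """All maximal runs where the reverse complement of ``guide`` matches
    ``transcript`` contiguously for at least ``min_len`` nt (U = T).

    Returns matches sorted by length (longest first).  Sequences shorter than
    ``min_len`` yield an empty list with a warning.
    """
    g = reverse_complement(guide)
    t = _validate_seq(transcript, "transcript").replace("U", "T")
    if len(g) < min_len or len(t) < min_len:
        warnings.warn("sequence shorter than min_len; no scan performed", stacklevel=2)
        return []
    ga = np.frombuffer(g.encode(), dtype=np.uint8)
    ta = np.frombuffer(t.encode(), dtype=np.uint8)
    n, m = ga.size, ta.size
    # run-length DP along diagonals, row by row (n is guide-sized, small)
    prev = np.zeros(m, dtype=np.int32)
    matches: list[Match] = []
    for i in range(n):
        eq = ga[i] == ta
        cur = np.zeros(m, dtype=np.int32)
        cur[0] = eq[0]
        cur[1:] = np.where(eq[1:], prev[:-1] + 1, 0)
        # a run ends at (i, j) if no extension exists at (i+1, j+1)
        if i + 1 < n:
            nxt_eq = ga[i + 1] == ta
            ended = (cur > 0) & ~np.concatenate([nxt_eq[1:], [False]])
        else:
            ended = cur > 0
        for j in np.where(ended & (cur >= min_len))[0]:
            L = int(cur[j])
            matches.append(
                Match(
                    length=L,
                    t_start=int(j - L + 2),
                    t_end=int(j + 1),
                    g_start=int(i - L + 2),
                    g_end=int(i + 1),
                )
            )
        prev = cur
    matches.sort(key=lambda mt: (-mt.length, mt.t_start))
    return matches


def attribute_to_single_sirna(
    primary_zm,
    secondary_zm,
    pool_a: str,
    pool_b: str,
    singles: list[str],
    r_min: float = 0.6,
) -> dict:
    """Attribute pool_a's similarity to pool_b to individual siRNAs.

    Each single siRNA of pool_a (rows of the secondary screen) is correlated
    with pool_b's primary response.  Two or more passing singles indicate a
    genuinely related function; exactly one passing single is the signature of
    an off-target reagent.
    """
    if not singles:
        return {"status": "unattributable", "correlations": {}, "passing": []}
    zb = primary_zm.z.loc[pool_b]
    corrs: dict[str, float] = {}
    for sid in singles:
        zs = secondary_zm.z.loc[sid]
        shared = zb.index.intersection(zs.index)
        xa = zs.loc[shared].to_numpy(float)
        xb = zb.loc[shared].to_numpy(float)
        if np.std(xa) == 0 or np.std(xb) == 0:
            corrs[sid] = np.nan
            continue
        corrs[sid] = float(stats.pearsonr(xa, xb)[0])
    passing = [sid for sid, r in corrs.items() if np.isfinite(r) and r >= r_min]
    if len(passing) >= 2:
        status = "related_function"
    elif len(passing) == 1:
        status = "off_target_candidate"
    else:
        status = "no_flag"
    return {"status": status, "correlations": corrs, "passing": passing}


def flag_offtargets(
    zm,
    lib: SirnaLibrary,
    hits: list[str],
    secondary_zm=None,
    r_min: float = 0.6,
    min_len: int = 11,
    well_known: list[str] | None = None,
) -> pd.DataFrame:
    """Flag hit pools whose activity is attributable to off-target silencing.

    For each hit pool A and each target gene B (default: all other hits, or a
    user-supplied ``well_known`` list), A is flagged against B when a guide of
    A shows >= ``min_len`` nt contiguous complementarity to B's transcript and
    the response criterion holds at r >= ``r_min`` — tested on that same
    single siRNA's secondary-screen row when available (confidence "single"),
    otherwise on the pool row (confidence "pool").  Correlation is evaluated
    first since it is cheap; sequence scans run only for correlated pairs.
    """
    targets = list(well_known) if well_known is not None else list(hits)
    report_rows = []
    for pool_a in hits:
        gene_a = lib.pools.get(pool_a, pool_a)
        guides = lib.guides_of_pool(pool_a)
        if not guides:
            continue
        for gene_b in targets:
            if gene_b == pool_a or lib.pools.get(gene_b, gene_b) == gene_a:
                continue
            transcript = lib.transcripts.get(lib.pools.get(gene_b, gene_b))
            if transcript is None:
                warnings.warn(
                    f"no transcript for candidate gene {gene_b}; pair skipped",
                    stacklevel=2,
                )
                continue
            try:
                pool_r = response_similarity(zm, pool_a, gene_b)
            except (KeyError, ValueError):
                continue
            for sid, g in guides.items():
                single_r = np.nan
                if secondary_zm is not None and sid in secondary_zm.z.index:
                    zb = zm.z.loc[gene_b]
                    zs = secondary_zm.z.loc[sid]
                    shared = zb.index.intersection(zs.index)
                    if len(shared) >= 10 and np.std(zs.loc[shared]) > 0:
                        single_r = float(
                            stats.pearsonr(zs.loc[shared], zb.loc[shared])[0]
                        )
                    evidence_r, confidence = single_r, "single"
                else:
                    evidence_r, confidence = pool_r, "pool"
                if not (np.isfinite(evidence_r) and evidence_r >= r_min):
                    continue
                found = complementarity_scan(g, transcript, min_len=min_len)
                if not found:
                    continue
                best = found[0]
                report_rows.append(
                    {
                        "pool_id": pool_a,
                        "suspect_sirna_id": sid,
                        "offended_gene": gene_b,
                        "match_length": best.length,
                        "match_start": best.t_start,
                        "match_end": best.t_end,
                        "pool_pool_correlation": pool_r,
                        "single_vs_pool_correlation": single_r,
                        "confidence": confidence,
                    }
                )
    cols = [
        "pool_id",
        "suspect_sirna_id",
        "offended_gene",
        "match_length",
        "match_start",
        "match_end",
        "pool_pool_correlation",
        "single_vs_pool_correlation",
        "confidence",
    ]
    return pd.DataFrame(report_rows, columns=cols)
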