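"""Pairwise synonymous/non-synonymous substitution rates by the method of
Nei & Gojobori (1986) with Jukes-Cantor correction, plus the cross-category
Kruskal-Wallis comparison of omega (= dn/ds) values.

Counting uses the bacterial/plastid genetic code (NCBI translation table 11).
Synonymous site fractions per codon enumerate the three alternative bases at
each position; a change producing a stop codon counts as non-synonymous, so
site counts conserve N + S = 3 * codons exactly.  Multi-difference codons are
scored by averaging over all orderings of single-base steps, excluding
pathways that pass through a stop codon (all orderings are used only if every
one is blocked).  Gap- or ambiguity-containing codons are masked pairwise
before counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

_BASES = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[11]
_STOPS = frozenset(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)


def translate_codon(codon: str) -> str | None:
    """Amino acid for a codon under table 11; None for a stop codon."""
    return _AA.get(codon)


@dataclass(frozen=True)
class GeneRates:
    """NG86 estimates for one taxon-vs-reference pair of one gene."""

    gene: str
    taxon: str
    codons: int
    N: float  # non-synonymous sites
    S: float  # synonymous sites
    Nd: float  # pathway-averaged non-synonymous differences
    Sd: float
    pN: float
    pS: float
    dn: float  # Jukes-Cantor corrected; nan when correction undefined
    ds: float

    @property
    def omega(self) -> float:
        if math.isnan(self.dn) or math.isnan(self.ds) or self.ds == 0.0:
            return math.nan
        return self.dn / self.ds


def _is_clean_codon(codon: str) -> bool:
    return len(codon) == 3 and all(b in _BASES for b in codon)


def _syn_sites(codon: str) -> float:
    """Fraction-weighted synonymous site count of one codon (0..3)."""
    aa = _AA.get(codon)
    if aa is None:
        raise ValueError(f"stop codon {codon} has no site counts")
    s = 0.0
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            # stop-producing changes count as non-synonymous
            if _AA.get(mutant) == aa:
                s += 1.0 / 3.0
    return s


def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) contribution of one codon pair, averaged over orderings of
    the single-base steps; pathways through stop codons are excluded."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        current = c1
        sd = nd = 0.0
        blocked = False
        for step, pos in enumerate(order):
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in _STOPS and step < len(order) - 1:
                blocked = True  # intermediate stop; endpoints are validated
            if _AA.get(current) is not None and _AA.get(nxt) == _AA.get(current):
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        paths.append((blocked, sd, nd))
    valid = [(sd, nd) for blocked, sd, nd in paths if not blocked]
    if not valid:
        valid = [(sd, nd) for _, sd, nd in paths]
    sd = sum(v[0] for v in valid) / len(valid)
    nd = sum(v[1] for v in valid) / len(valid)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4) ln(1 - (4/3) p); nan when p >= 3/4."""
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_pair(
    seq1: str, seq2: str, gene: str = "", taxon: str = ""
) -> GeneRates:
    """NG86 rates for one pair of aligned coding sequences.

    Sequences must be equal length and a multiple of 3.  Codon pairs where
    either codon contains a gap or ambiguous base are masked.  Internal stop
    codons (in unmasked codons) raise a ValidationError.
    """
    from .formats_io import ValidationError

    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ValidationError(f"{gene}/{taxon}: unequal sequence lengths")
    if len(seq1) % 3 != 0:
        raise ValidationError(f"{gene}/{taxon}: length not divisible by 3")
    codon_pairs = []
    n_codons_total = len(seq1) // 3
    for i in range(n_codons_total):
        c1, c2 = seq1[3 * i : 3 * i + 3], seq2[3 * i : 3 * i + 3]
        if not (_is_clean_codon(c1) and _is_clean_codon(c2)):
            continue
        # a terminal stop in the final codon of both is tolerated and masked
        if i == n_codons_total - 1 and (c1 in _STOPS or c2 in _STOPS):
            continue
        if c1 in _STOPS or c2 in _STOPS:
            raise ValidationError(
                f"{gene}/{taxon}: internal stop codon at codon {i + 1}"
            )
        codon_pairs.append((c1, c2))

    L = len(codon_pairs)
    s1 = sum(_syn_sites(c1) for c1, _ in codon_pairs)
    s2 = sum(_syn_sites(c2) for _, c2 in codon_pairs)
    S = (s1 + s2) / 2.0
    N = 3.0 * L - S
    Sd = Nd = 0.0
    for c1, c2 in codon_pairs:
        sd, nd = _pair_differences(c1, c2)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    return GeneRates(
        gene=gene,
        taxon=taxon,
        codons=L,
        N=N,
        S=S,
        Nd=Nd,
        Sd=Sd,
        pN=pN,
        pS=pS,
        dn=jukes_cantor(pN),
        ds=jukes_cantor(pS),
    )


def rates_to_frame(rates: list[GeneRates]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "taxon": r.taxon,
                "codons": r.codons,
                "N": r.N,
                "S": r.S,
                "Nd": r.Nd,
                "Sd": r.Sd,
                "dn": r.dn,
                "ds": r.ds,
                "omega": r.omega,
            }
            for r in rates
        ]
    )


def filter_high_ds(rates_table: pd.DataFrame, n_remove: int = 35) -> pd.DataFrame:
    """Drop the n_remove genes with the highest mean ds across taxa.

    Mirrors the screen that removes saturated genes before comparing omega
    (35 of 68 genes in the reference analysis); ties broken by gene name for
    determinism.  n_remove = 0 is the identity.
    """
    from .formats_io import ValidationError

    genes = rates_table["gene"].unique()
    if n_remove >= len(genes):
        raise ValidationError(
            f"cannot remove {n_remove} of {len(genes)} genes"
        )
    if n_remove == 0:
        return rates_table.copy()
    mean_ds = rates_table.groupby("gene")["ds"].mean()

    def sort_key(g: str):
        m = mean_ds[g]
        # a NaN mean ds means the JC correction was undefined (p >= 3/4),
        # i.e. saturation: rank such genes above every finite value
        return (-(m if not math.isnan(m) else math.inf), g)

    ranked = sorted(mean_ds.index, key=sort_key)
    removed = set(ranked[:n_remove])
    return rates_table[~rates_table["gene"].isin(removed)].copy()


@dataclass(frozen=True)
class KWResult:
    """Tie-corrected Kruskal-Wallis H with chi-square upper-tail p-value."""

    H: float
    df: int
    p_value: float


def kruskal_wallis(groups: list[list[float]]) -> KWResult:
    """H = [12/(N(N+1))] * sum n_i (Rbar_i - (N+1)/2)^2, divided by the tie
    correction 1 - sum(t^3 - t)/(N^3 - N); p from the chi-square upper tail
    at k-1 degrees of freedom.  All-identical values give H = 0, p = 1."""
    from .formats_io import ValidationError

    k = len(groups)
    if k < 2:
        raise ValidationError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValidationError("empty group")
    values = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n_total = len(values)
    if n_total < k:
        raise ValidationError("need N >= k observations")
    ranks = stats.rankdata(values)
    h = 0.0
    offset = 0
    for g in groups:
        n_i = len(g)
        rbar = ranks[offset : offset + n_i].mean()
        h += n_i * (rbar - (n_total + 1) / 2.0) ** 2
        offset += n_i
    h *= 12.0 / (n_total * (n_total + 1))
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_term / (n_total**3 - n_total)
    if denom <= 0.0:  # every value identical
        return KWResult(H=0.0, df=k - 1, p_value=1.0)
    h /= denom
    p = float(stats.chi2.sf(h, df=k - 1))
    return KWResult(H=h, df=k - 1, p_value=min(max(p, np.nextafter(0, 1)), 1.0))


def category_rate_comparison(
    rates_table: pd.DataFrame, categories: dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare omega across pathway categories, per gene and pooled.

    Returns (per_gene, pooled): per_gene holds category means of dn and ds
    plus the Kruskal-Wallis H and p over omega values (NaN-omega taxa are
    dropped; the test is skipped with a warning-equivalent NaN when fewer
    than two categories retain >= 2 taxa); pooled holds per-category dn/ds
    summaries over all genes.  Raises when only one category is present.
    """
    from .formats_io import ValidationError

    cats = sorted(set(categories.values()))
    if len(cats) < 2:
        raise ValidationError("need at least two pathway categories to compare")
    missing = set(rates_table["taxon"]) - set(categories)
    if missing:
        raise ValidationError(f"taxa without category label: {sorted(missing)}")
    table = rates_table.copy()
    table["category"] = table["taxon"].map(categories)

    per_gene_rows = []
    for gene, sub in table.groupby("gene", sort=True):
        row: dict[str, object] = {"gene": gene}
        for cat in cats:
            cat_sub = sub[sub["category"] == cat]
            row[f"dn_mean_{cat}"] = cat_sub["dn"].mean()
            row[f"ds_mean_{cat}"] = cat_sub["ds"].mean()
        groups = [
            sub.loc[
                (sub["category"] == cat) & sub["omega"].notna(), "omega"
            ].tolist()
            for cat in cats
        ]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) >= 2:
            kw = kruskal_wallis(groups)
            row["kw_H"], row["kw_p"] = kw.H, kw.p_value
        else:
            row["kw_H"], row["kw_p"] = math.nan, math.nan
        per_gene_rows.append(row)
    per_gene = pd.DataFrame(per_gene_rows)

    pooled = (
        table.groupby("category")[["dn", "ds"]]
        .agg(["mean", "median", "count"])
        .reset_index()
    )
    pooled.columns = ["_".join(c).rstrip("_") for c in pooled.columns]
    return per_gene, pooled
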