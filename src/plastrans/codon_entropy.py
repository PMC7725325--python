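"""Information entropy of amino acid (IEA): randomness of synonymous codon usage.

For each amino-acid category *i* with ``n_i`` synonymous codons (n_i >= 2),
the IEA is the Shannon entropy of the observed synonymous-codon frequencies
``p_ij``, taken with logarithm base ``n_i`` so the statistic lies in [0, 1]:

    IEA_i = sum_j p_ij * log_{n_i}(1 / p_ij)

IEA = 1 when every synonymous codon is used equally often; IEA = 0 when a
single codon is used exclusively.  Under the bacterial genetic code there are
19 categories: the 18 amino acids encoded by more than one codon, plus one
"stop amino acid" category pooling the three stop codons.  A plasmid genome
resident in a single host tends to inherit that host's codon preferences
(low IEA); a plasmid that moves between hosts accumulates mixed preferences
(high IEA), which is the signal this module quantifies.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

__all__ = [
    "GeneticCode",
    "CodonCounts",
    "IEAProfile",
    "build_genetic_code",
    "count_synonymous_codons",
    "iea",
    "iea_profile",
    "find_orfs",
    "compare_groups",
]

logger = logging.getLogger(__name__)

STOP_SYMBOL = "*"
DNA_BASES = "ACGT"
IUPAC_DNA = set("ACGTRYSWKMBDHVN")
_CLAMP = 1e-12


@dataclass(frozen=True)
class GeneticCode:
    """A translation table with stop codons pooled into one category.

    ``categories`` lists, in a fixed order, every amino-acid symbol with two
    or more synonymous codons (single-codon amino acids such as Met and Trp
    under table 11 are excluded; the pooled stop category ``*`` is included).
    """

    table_id: int
    codon_to_aa: dict[str, str]
    categories: tuple[str, ...]

    @property
    def synonymous_codons(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {aa: [] for aa in self.categories}
        for codon in sorted(self.codon_to_aa):
            aa = self.codon_to_aa[codon]
            if aa in out:
                out[aa].append(codon)
        return {aa: tuple(codons) for aa, codons in out.items()}

    def n_codons(self, category: str) -> int:
        return len(self.synonymous_codons[category])


@dataclass
class CodonCounts:
    """Observed synonymous-codon tallies, one integer vector per category."""

    counts: dict[str, np.ndarray]
    total_codons: int = 0


@dataclass
class IEAProfile:
    """Per-genome IEA values, one per category; NaN marks an unobserved category."""

    genome_id: str
    iea: dict[str, float] = field(default_factory=dict)
    label: str | None = None


def build_genetic_code(table_id: int = 11) -> GeneticCode:
    """Build the category structure of a translation table.

    Parameters
    ----------
    table_id : NCBI translation table number (default 11, bacterial).

    Returns a :class:`GeneticCode` whose ``categories`` hold every amino acid
    with >= 2 synonymous codons plus the pooled stop category.  For the
    standard and bacterial codes this yields exactly 19 categories.
    """
    try:
        table = CodonTable.unambiguous_dna_by_id[table_id]
    except KeyError as exc:
        raise ValueError(f"unsupported translation table id: {table_id}") from exc
    codon_to_aa: dict[str, str] = {}
    for codon in ("".join(c) for c in itertools.product(DNA_BASES, repeat=3)):
        if codon in table.stop_codons:
            codon_to_aa[codon] = STOP_SYMBOL
        else:
            codon_to_aa[codon] = table.forward_table[codon]
    assert len(codon_to_aa) == 64
    degeneracy: dict[str, int] = {}
    for aa in codon_to_aa.values():
        degeneracy[aa] = degeneracy.get(aa, 0) + 1
    # Fixed reporting order: amino acids alphabetically, stop category last.
    aas = sorted(a for a, n in degeneracy.items() if n > 1 and a != STOP_SYMBOL)
    categories = tuple(aas) + ((STOP_SYMBOL,) if degeneracy.get(STOP_SYMBOL, 0) > 1 else ())
    return GeneticCode(table_id=table_id, codon_to_aa=codon_to_aa, categories=categories)


def _validate_dna(seq: str, record_name: str) -> None:
    bad = set(seq.upper()) - IUPAC_DNA
    if bad:
        raise ValueError(
            f"sequence {record_name!r} contains non-IUPAC characters: {sorted(bad)}"
        )


def count_synonymous_codons(cds_list: list[str], code: GeneticCode) -> CodonCounts:
    """Tally in-frame codons of coding sequences into their categories.

    Trailing partial codons are dropped with a warning; codons containing
    ambiguous bases are skipped.  Codons of single-codon amino acids count
    toward ``total_codons`` but have no category vector.
    """
    if not cds_list:
        raise ValueError("cds_list is empty")
    syn = code.synonymous_codons
    index = {
        codon: (aa, j) for aa, codons in syn.items() for j, codon in enumerate(codons)
    }
    counts = {aa: np.zeros(len(codons), dtype=np.int64) for aa, codons in syn.items()}
    total = 0
    for k, cds in enumerate(cds_list):
        seq = str(cds).upper().replace("U", "T")
        _validate_dna(seq, f"cds[{k}]")
        if len(seq) % 3:
            logger.warning("cds[%d]: dropping trailing partial codon (%d bp)", k, len(seq) % 3)
            seq = seq[: len(seq) - len(seq) % 3]
        for p in range(0, len(seq), 3):
            codon = seq[p : p + 3]
            if any(b not in DNA_BASES for b in codon):
                continue
            total += 1
            hit = index.get(codon)
            if hit is not None:
                aa, j = hit
                counts[aa][j] += 1
    return CodonCounts(counts=counts, total_codons=total)


def iea(counts_for_category: np.ndarray | list[int], n_i: int) -> float:
    """Normalized Shannon entropy of one category's synonymous-codon counts.

    Returns ``sum_j p_ij * log_{n_i}(1/p_ij)`` with the convention
    ``0 * log(1/0) = 0``.  All-zero counts return NaN (the category was not
    observed — a different statement than "usage is deterministic", which
    would be 0).
    """
    if n_i < 2:
        raise ValueError(f"n_i must be >= 2, got {n_i}")
    c = np.asarray(counts_for_category, dtype=float)
    if c.shape != (n_i,):
        raise ValueError(f"expected {n_i} counts, got shape {c.shape}")
    if np.any(c < 0):
        raise ValueError("negative codon counts")
    total = c.sum()
    if total == 0:
        return math.nan
    p = c[c > 0] / total
    value = float(-(p * np.log(p)).sum() / math.log(n_i))
    if value > 1.0:
        if value > 1.0 + _CLAMP:
            raise AssertionError(f"IEA overshoot beyond tolerance: {value}")
        value = 1.0
    return max(value, 0.0) + 0.0  # normalize -0.0


def profile_from_counts(counts: CodonCounts, code: GeneticCode,
                        genome_id: str = "", label: str | None = None) -> IEAProfile:
    """One IEA value per category of ``code`` from tallied counts."""
    values = {aa: iea(counts.counts[aa], code.n_codons(aa)) for aa in code.categories}
    return IEAProfile(genome_id=genome_id, iea=values, label=label)


def _cds_from_record(record: SeqRecord) -> list[str]:
    out = []
    for feat in record.features:
        if feat.type == "CDS":
            out.append(str(feat.extract(record.seq)))
    return out


def iea_profile(genome: SeqRecord, code: GeneticCode, *,
                orf_fallback: bool = True, min_codons: int = 60) -> IEAProfile:
    """IEA profile of one genome from its CDS annotations.

    If the record carries no CDS features and ``orf_fallback`` is enabled,
    ORFs of at least ``min_codons`` codons are predicted with
    :func:`find_orfs` and used instead.
    """
    cds = _cds_from_record(genome)
    if not cds and orf_fallback:
        cds = find_orfs(str(genome.seq), min_codons=min_codons)
    if not cds:
        raise ValueError(f"genome {genome.id!r} has no usable CDS or ORFs")
    counts = count_synonymous_codons(cds, code)
    label = genome.annotations.get("transmissibility") if genome.annotations else None
    return profile_from_counts(counts, code, genome_id=genome.id, label=label)


_START_CODONS = ("ATG", "GTG", "TTG")
_STOP_CODONS = ("TAA", "TAG", "TGA")


def find_orfs(sequence: str, min_codons: int = 60) -> list[str]:
    """Stop-closed ORFs on both strands, longest per stop-to-stop interval.

    Scans each of the six frames; within a frame, after every stop codon the
    first ATG/GTG/TTG opens an ORF that runs to the next stop codon
    (inclusive).  Open-ended runs without a closing stop are not reported.
    Returned sequences include the stop codon, and ``min_codons`` counts it.
    """
    if min_codons < 2:
        raise ValueError("min_codons must be >= 2")
    seq = str(sequence).upper()
    orfs: list[str] = []
    for strand_seq in (seq, str(Seq(seq).reverse_complement())):
        for offset in range(3):
            start: int | None = None
            for p in range(offset, len(strand_seq) - 2, 3):
                codon = strand_seq[p : p + 3]
                if codon in _STOP_CODONS:
                    if start is not None and (p + 3 - start) // 3 >= min_codons:
                        orfs.append(strand_seq[start : p + 3])
                    start = None
                elif start is None and codon in _START_CODONS:
                    start = p
    return orfs


def compare_groups(profiles_a: list[IEAProfile], profiles_b: list[IEAProfile],
                   code: GeneticCode | None = None,
                   exact_max_n: int = 25) -> pd.DataFrame:
    """Per-category comparison of two groups of IEA profiles.

    For each category: group means (NaN-excluded), the AUC of separating the
    groups on that single IEA (group a scored as positive, Mann–Whitney
    normalization with mid-rank ties), and the two-sided Wilcoxon rank-sum
    p-value (exact enumeration for tie-free groups of at most ``exact_max_n``
    profiles, normal approximation with tie correction otherwise).

    Returns a DataFrame with columns category, n_codons, mean_a, mean_b, auc,
    p_value, flag — row order matching ``code.categories``.  A category with
    no observations in one of the groups is flagged ``missing_in_group``.
    """
    if not profiles_a or not profiles_b:
        raise ValueError("both groups must be non-empty")
    if code is None:
        code = build_genetic_code(11)
    rows = []
    for aa in code.categories:
        a = np.array([p.iea.get(aa, math.nan) for p in profiles_a], dtype=float)
        b = np.array([p.iea.get(aa, math.nan) for p in profiles_b], dtype=float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        flag = ""
        if a.size == 0 or b.size == 0:
            rows.append((aa, code.n_codons(aa), float(a.mean()) if a.size else math.nan,
                         float(b.mean()) if b.size else math.nan,
                         math.nan, math.nan, "missing_in_group"))
            continue
        pooled = np.concatenate([a, b])
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (max(a.size, b.size) <= exact_max_n and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        auc = float(res.statistic) / (a.size * b.size)
        rows.append((aa, code.n_codons(aa), float(a.mean()), float(b.mean()),
                     auc, float(res.pvalue), flag))
    return pd.DataFrame(
        rows, columns=["category", "n_codons", "mean_a", "mean_b", "auc", "p_value", "flag"]
    )
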