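"""Synthetic benchmark generation: host codon-usage tables, plasmid-like
genomes, and random fragment extraction.

The generator operationalizes genome amelioration: a plasmid resident in one
host converges on that host's codon preferences, while a plasmid that moves
between hosts accumulates a mixture of preferences.  A non-transmissible
surrogate genome therefore draws every gene from a single host usage table;
a transmissible surrogate draws each gene from one of several divergent
tables.  Fragments are extracted uniformly at random (position, length and
strand), error-free, mimicking artificial contigs drawn from assembled
genomes, in the length strata used for evaluation: train/A 100–400 bp,
B 401–800 bp, C 801–1200 bp, D 5000–10000 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .codon_entropy import GeneticCode, build_genetic_code

__all__ = [
    "HostUsageTable",
    "SyntheticGenomeSpec",
    "Fragment",
    "GROUP_RANGES",
    "sample_usage_tables",
    "synth_genome",
    "extract_fragments",
    "build_benchmark",
]

TRANSMISSIBLE = "transmissible"
NON_TRANSMISSIBLE = "non-transmissible"

#: fragment length strata (bp, inclusive)
GROUP_RANGES: dict[str, tuple[int, int]] = {
    "train": (100, 400),
    "A": (100, 400),
    "B": (401, 800),
    "C": (801, 1200),
    "D": (5000, 10000),
}

# Residues sampled for synthetic genes: the 20 standard amino acids.  Single
# codon residues (M, W under table 11) keep the composition realistic even
# though they carry no entropy signal.
_RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class HostUsageTable:
    """Per-category synonymous-codon probabilities for one host.

    ``usage`` maps each degenerate amino-acid category (including the pooled
    stop category) to a probability vector over its synonymous codons, in
    the genetic code's codon order.  ``gc_bias`` sets intergenic base
    composition.
    """

    usage: dict[str, np.ndarray]
    gc_bias: float = 0.5
    code: GeneticCode = field(default_factory=lambda: build_genetic_code(11))

    def __post_init__(self) -> None:
        for aa, p in self.usage.items():
            if abs(float(np.sum(p)) - 1.0) > 1e-9 or np.any(np.asarray(p) < 0):
                raise ValueError(f"usage vector for {aa!r} is not a probability vector")
        if not 0.0 < self.gc_bias < 1.0:
            raise ValueError("gc_bias must be in (0, 1)")


@dataclass
class SyntheticGenomeSpec:
    """Recipe for one labeled synthetic plasmid genome."""

    n_genes: int
    usage_mixture: list[tuple[HostUsageTable, float]]
    label: str
    seed: int
    gene_len_codons: tuple[int, int] = (100, 300)
    intergenic_frac: float = 0.10
    genome_id: str = ""
    #: "codon": every codon drawn from the convex blend of the component
    #: tables (amelioration acting genome-wide; the default).  "gene": one
    #: component chosen per gene (HGT-acquired whole genes).
    mixing: str = "codon"

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        weights = [w for _, w in self.usage_mixture]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if not 0.0 <= self.intergenic_frac < 1.0:
            raise ValueError("intergenic_frac must be in [0, 1)")
        k = len(self.usage_mixture)
        if self.label == TRANSMISSIBLE and k < 2:
            raise ValueError("transmissible surrogates need >= 2 mixture components")
        if self.label == NON_TRANSMISSIBLE and k != 1:
            raise ValueError("non-transmissible surrogates use exactly 1 component")
        if self.mixing not in ("codon", "gene"):
            raise ValueError(f"mixing must be 'codon' or 'gene', got {self.mixing!r}")


@dataclass
class Fragment:
    """A labeled subsequence extracted from a genome (0-based, half-open)."""

    sequence: str
    label: str
    genome_id: str
    start: int
    strand: str
    group: str = "train"
    fragment_id: str = ""

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


def sample_usage_tables(k: int, divergence: float, seed: int,
                        code: GeneticCode | None = None) -> list[HostUsageTable]:
    """Draw ``k`` host usage tables with controllable mutual divergence.

    Each table interpolates between a shared random (Dirichlet) baseline and
    a table-specific near-deterministic preference, with distinct preferred
    codons assigned round-robin across tables.  ``divergence=0`` gives k
    identical tables; ``divergence=1`` gives near-deterministic, mutually
    distinct codon preferences.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    if code is None:
        code = build_genetic_code(11)
    rng = np.random.default_rng(seed)
    shared = {
        aa: rng.dirichlet(np.full(code.n_codons(aa), 5.0))
        for aa in code.categories
    }
    # Distinct preferred codons per table where degeneracy allows.
    offsets = {aa: int(rng.integers(code.n_codons(aa))) for aa in code.categories}
    eps = 0.02
    tables = []
    for t in range(k):
        usage = {}
        for aa in code.categories:
            n = code.n_codons(aa)
            pref = np.full(n, eps / n)
            pref[(offsets[aa] + t) % n] += 1.0 - eps
            v = (1.0 - divergence) * shared[aa] + divergence * pref
            usage[aa] = v / v.sum()
        gc = float(rng.uniform(0.35, 0.65))
        tables.append(HostUsageTable(usage=usage, gc_bias=gc, code=code))
    return tables


def _draw_gene(rng: np.random.Generator, table: HostUsageTable,
               n_codons: int) -> str:
    """One gene: ATG, then codons from the table, then a stop codon."""
    code = table.code
    syn = code.synonymous_codons
    parts = ["ATG"]
    for _ in range(n_codons - 2):
        aa = _RESIDUES[rng.integers(len(_RESIDUES))]
        if aa in table.usage:
            codons = syn[aa]
            j = rng.choice(len(codons), p=table.usage[aa])
            parts.append(codons[j])
        else:  # single-codon residue (M, W under table 11)
            parts.append(next(c for c, a in code.codon_to_aa.items() if a == aa))
    stop_codons = syn["*"]
    parts.append(stop_codons[rng.choice(len(stop_codons), p=table.usage["*"])])
    return "".join(parts)


def _draw_spacer(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _blend_tables(mixture: list[tuple[HostUsageTable, float]]) -> HostUsageTable:
    code = mixture[0][0].code
    usage = {
        aa: sum(w * t.usage[aa] for t, w in mixture)
        for aa in mixture[0][0].usage
    }
    usage = {aa: v / v.sum() for aa, v in usage.items()}
    gc = sum(w * t.gc_bias for t, w in mixture)
    return HostUsageTable(usage=usage, gc_bias=gc, code=code)


def synth_genome(spec: SyntheticGenomeSpec) -> SeqRecord:
    """Generate one labeled genome with CDS annotations, deterministic in the seed.

    Under the default ``mixing="codon"`` every codon is drawn from the convex
    blend of the component tables; under ``mixing="gene"`` each gene is drawn
    whole from one component chosen with the spec weights.  Intergenic
    spacers use the blended GC bias.
    """
    rng = np.random.default_rng(spec.seed)
    tables = [t for t, _ in spec.usage_mixture]
    weights = np.array([w for _, w in spec.usage_mixture])
    blended = _blend_tables(spec.usage_mixture)
    lo, hi = spec.gene_len_codons
    gene_lengths = rng.integers(lo, hi + 1, size=spec.n_genes)
    if spec.mixing == "codon":
        genes = [_draw_gene(rng, blended, n) for n in gene_lengths]
    else:
        genes = [
            _draw_gene(rng, tables[rng.choice(len(tables), p=weights)], n)
            for n in gene_lengths
        ]
    coding_bp = sum(len(g) for g in genes)
    f = spec.intergenic_frac
    spacer_total = int(round(coding_bp * f / (1.0 - f)))
    # n_genes + 1 spacer slots (ends included), lengths multinomial-even.
    slots = spec.n_genes + 1
    spacer_lengths = rng.multinomial(spacer_total, np.full(slots, 1.0 / slots))
    gc = blended.gc_bias
    parts, features, pos = [], [], 0
    for i, gene in enumerate(genes):
        spacer = _draw_spacer(rng, int(spacer_lengths[i]), gc)
        parts.append(spacer)
        pos += len(spacer)
        features.append(
            SeqFeature(SimpleLocation(pos, pos + len(gene), strand=1), type="CDS")
        )
        parts.append(gene)
        pos += len(gene)
    parts.append(_draw_spacer(rng, int(spacer_lengths[-1]), gc))
    genome_id = spec.genome_id or f"synth_{spec.label}_{spec.seed}"
    record = SeqRecord(
        Seq("".join(parts)), id=genome_id, name=genome_id,
        description=f"synthetic {spec.label} plasmid surrogate",
        features=features,
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular"
    record.annotations["transmissibility"] = spec.label
    return record


def extract_fragments(genome: SeqRecord, length_range: tuple[int, int], n: int,
                      seed: int, group: str = "train") -> list[Fragment]:
    """Extract ``n`` random fragments from a genome.

    Start positions uniform over valid offsets, lengths uniform over
    ``length_range`` (inclusive), strand uniform; fragments are error-free
    copies and inherit the genome's transmissibility label.
    """
    lo, hi = length_range
    L = len(genome.seq)
    if L < lo:
        raise ValueError(f"genome {genome.id!r} ({L} bp) shorter than minimum fragment ({lo} bp)")
    if L < hi:
        raise ValueError(f"genome {genome.id!r} ({L} bp) shorter than maximum fragment ({hi} bp)")
    rng = np.random.default_rng(seed)
    label = genome.annotations.get("transmissibility", "")
    seq = str(genome.seq).upper()
    out = []
    lengths = rng.integers(lo, hi + 1, size=n)
    for i, flen in enumerate(lengths):
        start = int(rng.integers(0, L - flen + 1))
        frag = seq[start : start + flen]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = str(Seq(frag).reverse_complement())
        out.append(Fragment(
            sequence=frag, label=label, genome_id=genome.id, start=start,
            strand=strand, group=group,
            fragment_id=f"{genome.id}|{group}|{i}",
        ))
    return out


def synthetic_cohort(n_per_class_per_split: int, *, n_hosts: int = 2,
                     divergence: float = 1.0, seed: int = 0, n_genes: int = 20,
                     gene_len_codons: tuple[int, int] = (100, 300),
                     intergenic_frac: float = 0.10,
                     mixing: str = "codon") -> list[SeqRecord]:
    """A labeled, split cohort of synthetic genomes ready for benchmarking.

    Draws ``n_hosts`` usage tables at the given divergence, then builds
    ``n_per_class_per_split`` genomes per class for each of the train and
    test splits: non-transmissible surrogates cycle through single host
    tables, transmissible surrogates use 50/50 mixtures of consecutive
    table pairs.  Split and label are recorded in record annotations.
    """
    tables = sample_usage_tables(max(n_hosts, 2), divergence, seed)
    k = len(tables)
    genomes = []
    g = 0
    for split in ("train", "test"):
        for label in (TRANSMISSIBLE, NON_TRANSMISSIBLE):
            for i in range(n_per_class_per_split):
                if label == TRANSMISSIBLE:
                    mixture = [(tables[g % k], 0.5), (tables[(g + 1) % k], 0.5)]
                else:
                    mixture = [(tables[g % k], 1.0)]
                spec = SyntheticGenomeSpec(
                    n_genes=n_genes, usage_mixture=mixture, label=label,
                    seed=seed + 1000 + g, gene_len_codons=gene_len_codons,
                    intergenic_frac=intergenic_frac, mixing=mixing,
                    genome_id=f"{split}_{'T' if label == TRANSMISSIBLE else 'N'}{i}",
                )
                rec = synth_genome(spec)
                rec.annotations["split"] = split
                genomes.append(rec)
                g += 1
    return genomes


@dataclass
class BenchmarkConfig:
    """Fragment counts per class and split for :func:`build_benchmark`.

    Defaults are the full-scale study conditions; pass smaller counts for
    desk-scale runs.
    """

    n_train_per_class: int = 300_000
    n_test_per_class: dict[str, int] = field(
        default_factory=lambda: {"A": 30_000, "B": 30_000, "C": 30_000, "D": 10_000}
    )
    seed: int = 0


def build_benchmark(genomes: list[SeqRecord], config: BenchmarkConfig | None = None,
                    splits: dict[str, str] | None = None,
                    ) -> tuple[list[Fragment], dict[str, list[Fragment]], pd.DataFrame]:
    """Build class-balanced train and grouped test fragment sets.

    ``splits`` maps genome id to "train" or "test" (defaulting to the
    record's ``annotations["split"]``); no genome contributes to both.
    Fragments are allocated evenly over each class's genomes.  Returns
    (train fragments, {group: fragments}, manifest DataFrame).
    """
    config = config or BenchmarkConfig()
    splits = splits or {}

    def split_of(rec: SeqRecord) -> str:
        s = splits.get(rec.id) or rec.annotations.get("split")
        if s not in ("train", "test"):
            raise ValueError(f"genome {rec.id!r} has no train/test split assignment")
        return s

    by = {("train", TRANSMISSIBLE): [], ("train", NON_TRANSMISSIBLE): [],
          ("test", TRANSMISSIBLE): [], ("test", NON_TRANSMISSIBLE): []}
    for rec in genomes:
        label = rec.annotations.get("transmissibility")
        if label not in (TRANSMISSIBLE, NON_TRANSMISSIBLE):
            raise ValueError(f"genome {rec.id!r} has no transmissibility label")
        by[(split_of(rec), label)].append(rec)
    for (split, label), recs in by.items():
        if not recs:
            raise ValueError(f"no {label} genomes in the {split} split")

    rng = np.random.default_rng(config.seed)

    def sample(recs: list[SeqRecord], total: int, rng_: np.random.Generator,
               group: str) -> list[Fragment]:
        per = np.full(len(recs), total // len(recs))
        per[: total % len(recs)] += 1
        frags = []
        for rec, n in zip(recs, per):
            if n:
                frags.extend(extract_fragments(
                    rec, GROUP_RANGES[group], int(n),
                    seed=int(rng_.integers(2**31)), group=group,
                ))
        return frags

    train: list[Fragment] = []
    for label in (TRANSMISSIBLE, NON_TRANSMISSIBLE):
        train.extend(sample(by[("train", label)], config.n_train_per_class, rng, "train"))
    test: dict[str, list[Fragment]] = {}
    for group, n in config.n_test_per_class.items():
        test[group] = []
        for label in (TRANSMISSIBLE, NON_TRANSMISSIBLE):
            test[group].extend(sample(by[("test", label)], n, rng, group))

    rows = [
        (f.fragment_id, f.genome_id, f.start, f.end, f.strand,
         len(f.sequence), f.label, f.group)
        for f in train + [f for g in test.values() for f in g]
    ]
    manifest = pd.DataFrame(rows, columns=[
        "fragment_id", "genome_id", "start", "end", "strand", "length", "label", "group",
    ])
    return train, test, manifest
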