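"""Sequence encodings for the fragment classifier.

A DNA fragment is presented to the network through two parallel views:

* the *connected six-frame triplet sequence* — the fragment is read in all
  three forward frames and all three reverse-complement frames, each frame
  yielding a run of triplets; the six runs are concatenated (frames 1–3,
  then 4–6) and each triplet is one-hot encoded over the 64 codons
  (lexicographic order, AAA -> bit 0, AAC -> bit 1, ..., TTT -> bit 63);
* the *connected dual-strand base sequence* — the positive strand followed
  by the complementary strand (reverse complement, read 5'->3'), each base
  one-hot encoded with A=[0,0,0,1], C=[0,0,1,0], G=[0,1,0,0], T=[1,0,0,0].

Triplets or bases containing ambiguity codes encode to all-zero rows.
Matrices are zero-padded at the end to the fixed shapes implied by a maximum
fragment length, with true segment lengths recorded so downstream pooling
can mask the padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TripletCodeSequence",
    "EncodedFragment",
    "reverse_complement",
    "six_frame_triplets",
    "onehot_triplet_sequence",
    "encode_bases",
    "encode_fragment",
    "triplet_frame_lengths",
    "connected_triplet_length",
]

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)
_IUPAC = set("ACGTRYSWKMBDHVN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
# Printed 4-bit base codes, row order A, C, G, T.
_BASE_CODES = np.array(
    [[0, 0, 0, 1], [0, 0, 1, 0], [0, 1, 0, 0], [1, 0, 0, 0]], dtype=np.float32
)


def _check_dna(sequence: str) -> str:
    seq = str(sequence).upper()
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC DNA characters: {sorted(bad)}")
    return seq


def reverse_complement(sequence: str) -> str:
    """Reverse complement with IUPAC ambiguity codes mapped to their complements."""
    seq = str(sequence)
    if set(seq.upper()) - _IUPAC:
        raise ValueError(f"non-IUPAC DNA characters: {sorted(set(seq.upper()) - _IUPAC)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TripletCodeSequence:
    """Six per-frame triplet lists and their concatenation."""

    frames: list[list[str]]

    @property
    def connected(self) -> list[str]:
        return [t for frame in self.frames for t in frame]

    @property
    def frame_lengths(self) -> list[int]:
        return [len(f) for f in self.frames]


def triplet_frame_lengths(length: int) -> list[int]:
    """Triplet counts of the six frames of a fragment of ``length`` bp."""
    fwd = [(length - off) // 3 for off in range(3)]
    return fwd + fwd


def connected_triplet_length(length: int) -> int:
    return sum(triplet_frame_lengths(length))


def six_frame_triplets(sequence: str) -> TripletCodeSequence:
    """Expand a fragment into its six triplet code sequences.

    Frames 1–3 read the positive strand at offsets 0/1/2; frames 4–6 read
    the reverse complement the same way.  E.g. ``GCATTACGGCA`` gives frame 1
    ``GCA TTA CGG``, frame 2 ``CAT TAC GGC``, ..., frame 6 ``CCG TAA TGC``.
    """
    seq = _check_dna(sequence)
    if len(seq) < 3:
        raise ValueError(f"sequence shorter than one triplet: {len(seq)} bp")
    frames = []
    for strand in (seq, reverse_complement(seq)):
        for off in range(3):
            n = (len(strand) - off) // 3
            frames.append([strand[off + 3 * k : off + 3 * k + 3] for k in range(n)])
    return TripletCodeSequence(frames=frames)


def triplet_index(triplet: str) -> int:
    """Lexicographic codon index (A<C<G<T); -1 for any ambiguous triplet."""
    idx = 0
    for b in triplet:
        v = _BASE_INDEX.get(b)
        if v is None:
            return -1
        idx = idx * 4 + v
    return idx


def onehot_triplet_sequence(triplets: TripletCodeSequence | list[str]) -> np.ndarray:
    """T×64 one-hot matrix over the connected triplet sequence."""
    seq = triplets.connected if isinstance(triplets, TripletCodeSequence) else list(triplets)
    mat = np.zeros((len(seq), 64), dtype=np.float32)
    for row, trip in enumerate(seq):
        idx = triplet_index(trip)
        if idx >= 0:
            mat[row, idx] = 1.0
    return mat


def encode_bases(sequence: str) -> np.ndarray:
    """2L×4 one-hot matrix: positive strand rows, then complementary-strand rows."""
    seq = _check_dna(sequence)
    if not seq:
        raise ValueError("empty sequence")
    both = seq + reverse_complement(seq)
    mat = np.zeros((2 * len(seq), 4), dtype=np.float32)
    for row, base in enumerate(both):
        j = _BASE_INDEX.get(base)
        if j is not None:
            mat[row] = _BASE_CODES[j]
    return mat


@dataclass
class EncodedFragment:
    """The padded matrix pair fed to the classifier.

    ``triplet_matrix`` is Tmax×64 over the connected six-frame triplet
    sequence, ``base_matrix`` 2·Lmax×4 over the dual-strand base sequence;
    zero rows pad up to the fixed shapes.  ``length`` is the true fragment
    length in bp, from which the per-segment true lengths follow.
    """

    triplet_matrix: np.ndarray
    base_matrix: np.ndarray
    source_id: str
    length: int
    max_len: int

    @property
    def n_triplets(self) -> int:
        return connected_triplet_length(self.length)


def encode_fragment(sequence: str, max_len: int = 400, *, min_len: int = 100,
                    source_id: str = "") -> EncodedFragment:
    """Encode one fragment into the padded (triplet, base) matrix pair."""
    seq = _check_dna(sequence)
    if not min_len <= len(seq) <= max_len:
        raise ValueError(
            f"fragment length {len(seq)} outside [{min_len}, {max_len}] bp"
        )
    t_rows = connected_triplet_length(max_len)
    triplet = np.zeros((t_rows, 64), dtype=np.float32)
    triplet[: connected_triplet_length(len(seq))] = onehot_triplet_sequence(
        six_frame_triplets(seq)
    )
    base = np.zeros((2 * max_len, 4), dtype=np.float32)
    base[: 2 * len(seq)] = encode_bases(seq)
    return EncodedFragment(
        triplet_matrix=triplet, base_matrix=base, source_id=source_id,
        length=len(seq), max_len=max_len,
    )
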