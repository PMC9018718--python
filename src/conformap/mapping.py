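"""Residue correspondences between wild-type and mutant protein forms.

In-frame duplications (e.g. AKT1 P68-C77dup) change the protein length, so
any comparison of "the same residue" across alleles needs an explicit
order-preserving map between author residue numbers.  The convention here:
the first copy of a duplicated block keeps the wild-type identity, the
second copy is new (unmapped on the wild-type side), and every downstream
residue shifts by the duplication length — e.g. for a 10-residue
duplication after residue 77 of a 480-residue protein, wild-type residue
308 corresponds to mutant residue 318.

For arbitrary in-frame events the map can instead be derived from a global
Needleman–Wunsch alignment with affine gap penalties and a deterministic
traceback (diagonal preferred, then gap-in-b, then gap-in-a), which places
tied gaps leftmost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "AlignmentParams",
    "ResidueMap",
    "global_align",
    "residue_map_from_alignment",
    "map_from_duplication",
]

_VALID = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class AlignmentParams:
    """Global-alignment scoring.  A gap of length k costs
    ``gap_open + k * gap_extend``; both penalties are non-positive."""

    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0

    def __post_init__(self):
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.match_score <= self.mismatch_score:
            raise ValueError("match_score must exceed mismatch_score")


@dataclass
class ResidueMap:
    """Order-preserving correspondence between two residue numberings.

    ``pairs`` is strictly increasing in both coordinates; residues absent
    from the other side live in ``unmapped_wt`` / ``unmapped_mut`` (for a
    duplication, the second copy of the block).
    """

    pairs: list[tuple[int, int]]
    unmapped_wt: set[int] = field(default_factory=set)
    unmapped_mut: set[int] = field(default_factory=set)

    def __post_init__(self):
        wt = [p[0] for p in self.pairs]
        mut = [p[1] for p in self.pairs]
        if sorted(set(wt)) != wt or sorted(set(mut)) != mut:
            raise ValueError("pairs must be strictly increasing on both sides")
        if self.unmapped_wt & set(wt) or self.unmapped_mut & set(mut):
            raise ValueError("unmapped sets must be disjoint from mapped pairs")

    @classmethod
    def identity(cls, indices: Sequence[int]) -> "ResidueMap":
        return cls([(i, i) for i in indices])

    @property
    def forward(self) -> dict[int, int]:
        return dict(self.pairs)

    @property
    def backward(self) -> dict[int, int]:
        return {m: w for w, m in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    def __getitem__(self, wt_index: int) -> int:
        try:
            return self.forward[wt_index]
        except KeyError:
            raise KeyError(f"wild-type residue {wt_index} is unmapped") from None

    def inverse(self) -> "ResidueMap":
        """Swap the two sides (mutant becomes the reference)."""
        return ResidueMap([(m, w) for w, m in self.pairs],
                          unmapped_wt=set(self.unmapped_mut),
                          unmapped_mut=set(self.unmapped_wt))

    # -- serialization: two-column TSV with a commented footer ----------
    def to_tsv(self, path: str | Path | None = None) -> str:
        lines = ["wt_index\tmut_index"]
        lines += [f"{w}\t{m}" for w, m in self.pairs]
        if self.unmapped_wt:
            lines.append("# unmapped_wt: " + ",".join(map(str, sorted(self.unmapped_wt))))
        if self.unmapped_mut:
            lines.append("# unmapped_mut: " + ",".join(map(str, sorted(self.unmapped_mut))))
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_tsv(cls, source: str | Path) -> "ResidueMap":
        if isinstance(source, Path) or ("\n" not in str(source) and Path(str(source)).is_file()):
            text = Path(source).read_text()
        else:
            text = str(source)
        pairs, un_wt, un_mut = [], set(), set()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("wt_index"):
                continue
            if line.startswith("#"):
                tag, _, rest = line[1:].partition(":")
                vals = {int(v) for v in rest.split(",") if v.strip()}
                if tag.strip() == "unmapped_wt":
                    un_wt = vals
                elif tag.strip() == "unmapped_mut":
                    un_mut = vals
                continue
            w, m = line.split("\t")
            pairs.append((int(w), int(m)))
        return cls(pairs, un_wt, un_mut)


def global_align(seq_a: str, seq_b: str,
                 params: AlignmentParams = AlignmentParams()
                 ) -> tuple[str, str]:
    """Optimal global alignment of two amino-acid sequences (Gotoh).

    Returns the two gapped sequences.  Ties are broken deterministically
    during traceback: diagonal first, then gap-in-b (consume seq_a), then
    gap-in-a (consume seq_b) — which yields leftmost gap placement.
    """
    for label, s in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not s:
            raise ValueError(f"{label} is empty")
        bad = set(s) - _VALID
        if bad:
            raise ValueError(f"{label} contains non-amino-acid characters {sorted(bad)}")

    n, m = len(seq_a), len(seq_b)
    go, ge = params.gap_open, params.gap_extend
    NEG = -np.inf
    # state 0 = diagonal (M), 1 = gap-in-b / consume a (Y), 2 = gap-in-a / consume b (X)
    M = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Y[i, 0] = go + ge * i
    for j in range(1, m + 1):
        X[0, j] = go + ge * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = params.match_score if seq_a[i - 1] == seq_b[j - 1] else params.mismatch_score
            M[i, j] = s + max(M[i - 1, j - 1], Y[i - 1, j - 1], X[i - 1, j - 1])
            Y[i, j] = max(M[i - 1, j] + go + ge, Y[i - 1, j] + ge, X[i - 1, j] + go + ge)
            X[i, j] = max(M[i, j - 1] + go + ge, Y[i, j - 1] + go + ge, X[i, j - 1] + ge)

    # traceback with fixed state preference M > Y > X at every tie
    i, j = n, m
    scores = (M[i, j], Y[i, j], X[i, j])
    state = int(np.argmax(scores))  # argmax returns the first (preferred) maximum
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            s = params.match_score if seq_a[i - 1] == seq_b[j - 1] else params.mismatch_score
            target = M[i, j] - s
            cand = (M[i - 1, j - 1], Y[i - 1, j - 1], X[i - 1, j - 1])
            i, j = i - 1, j - 1
        elif state == 1:
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            cand = (M[i - 1, j] + go + ge, Y[i - 1, j] + ge, X[i - 1, j] + go + ge)
            target = Y[i, j]
            i = i - 1
        else:
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            cand = (M[i, j - 1] + go + ge, Y[i, j - 1] + go + ge, X[i, j - 1] + ge)
            target = X[i, j]
            j = j - 1
        if i == 0 and j == 0:
            break
        if i == 0:
            state = 2
        elif j == 0:
            state = 1
        else:
            state = next(k for k in range(3) if np.isclose(cand[k], target))
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def residue_map_from_alignment(alignment: tuple[str, str],
                               wt_indices: Sequence[int],
                               mut_indices: Sequence[int]) -> ResidueMap:
    """Turn a gapped alignment into a ResidueMap over author numbering.

    ``wt_indices`` / ``mut_indices`` give the author residue numbers of the
    ungapped sequences, in order.
    """
    ga, gb = alignment
    if len(ga) != len(gb):
        raise ValueError("gapped sequences differ in length")
    na = sum(c != "-" for c in ga)
    nb = sum(c != "-" for c in gb)
    if na != len(wt_indices):
        raise ValueError(f"wt_indices has {len(wt_indices)} entries but the "
                         f"alignment has {na} wild-type residues")
    if nb != len(mut_indices):
        raise ValueError(f"mut_indices has {len(mut_indices)} entries but the "
                         f"alignment has {nb} mutant residues")
    pairs: list[tuple[int, int]] = []
    un_wt, un_mut = set(), set()
    ia = ib = 0
    for ca, cb in zip(ga, gb):
        if ca != "-" and cb != "-":
            pairs.append((wt_indices[ia], mut_indices[ib]))
            ia += 1
            ib += 1
        elif ca != "-":
            un_wt.add(wt_indices[ia])
            ia += 1
        else:
            un_mut.add(mut_indices[ib])
            ib += 1
    return ResidueMap(pairs, un_wt, un_mut)


def map_from_duplication(wt_length: int, dup_start: int, dup_end: int) -> ResidueMap:
    """ResidueMap for a tandem in-frame duplication of wt residues
    ``dup_start..dup_end`` (inclusive, author numbering from 1).

    Wild-type residues up to ``dup_end`` keep their numbers; those after
    shift by the block length.  Mutant residues ``dup_end+1 ..
    dup_end+length`` are the new (second) copy and are unmapped.
    """
    if not (1 <= dup_start <= dup_end <= wt_length):
        raise ValueError(
            f"invalid duplication range {dup_start}..{dup_end} for length {wt_length}")
    length = dup_end - dup_start + 1
    pairs = [(i, i if i <= dup_end else i + length) for i in range(1, wt_length + 1)]
    unmapped_mut = set(range(dup_end + 1, dup_end + length + 1))
    return ResidueMap(pairs, set(), unmapped_mut)
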