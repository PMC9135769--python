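"""De novo loop sequence enumeration, ranking, and splicing.

Short junction loops are drawn from a restricted alphabet of residues with
high loop propensity (G, D, P, S, T), helix-turn abundance (L), and
helix-capping roles (E, D, K). Three-residue loops use the 9-letter alphabet
{G, D, P, S, L, N, T, E, K} (729 sequences); four-residue loops drop E,
giving the 8-letter alphabet {G, D, P, S, L, N, T, K} (4096 sequences).

Candidates are ranked by a conformational-homogeneity score (lower = more
stable; see :mod:`topofold.ensemble_metrics`), the top k per junction kept,
and the two junctions' shortlists combined into a full Cartesian splice set
(50 × 50 = 2500 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from itertools import product
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "LoopAlphabet",
    "LoopCandidate",
    "SpliceSet",
    "ALPHABET_3",
    "ALPHABET_4",
    "loop_alphabet",
    "enumerate_loop_sequences",
    "score_candidates",
    "select_top_k",
    "splice_combinations",
    "read_candidates_tsv",
    "write_candidates_tsv",
    "write_spliced_fasta",
]

ALPHABET_3 = ("G", "D", "P", "S", "L", "N", "T", "E", "K")
ALPHABET_4 = ("G", "D", "P", "S", "L", "N", "T", "K")


@dataclass(frozen=True)
class LoopAlphabet:
    length: int
    residues: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("loop length must be >= 1")
        if len(set(self.residues)) != len(self.residues):
            raise ValueError(f"duplicate residues in alphabet: {self.residues}")

    @property
    def size(self) -> int:
        return len(self.residues) ** self.length


@dataclass(frozen=True)
class LoopCandidate:
    junction: str
    sequence: str
    score: float | None = None

    def __post_init__(self) -> None:
        if self.score is not None and self.score < 0:
            raise ValueError(f"{self.sequence}: score must be >= 0, got {self.score}")


@dataclass(frozen=True)
class SpliceSet:
    pairs: tuple[tuple[LoopCandidate, LoopCandidate], ...]

    def __len__(self) -> int:
        return len(self.pairs)


def loop_alphabet(length: int) -> LoopAlphabet:
    """The built-in loop-propensity alphabet for 3- or 4-residue loops."""
    if length == 3:
        return LoopAlphabet(3, ALPHABET_3)
    if length == 4:
        return LoopAlphabet(4, ALPHABET_4)
    raise ValueError(
        f"no built-in alphabet for length {length}; supply a custom LoopAlphabet"
    )


def enumerate_loop_sequences(alphabet: LoopAlphabet) -> list[str]:
    """All |residues|^length sequences, lexicographic, no duplicates."""
    letters = sorted(alphabet.residues)
    return ["".join(p) for p in product(letters, repeat=alphabet.length)]


def score_candidates(
    candidates: Iterable[LoopCandidate],
    scorer: Callable[[LoopCandidate], float] | Mapping[str, float],
) -> list[LoopCandidate]:
    """Attach scores from a callable or a sequence→score mapping.

    Scoring is pluggable: the intended scorer computes the
    conformational-homogeneity metric on a per-candidate coordinate ensemble
    (ensembles in, ranking out); any callable returning a non-negative float
    works.
    """
    if isinstance(scorer, Mapping):
        lookup = scorer
        return [replace(c, score=float(lookup[c.sequence])) for c in candidates]
    return [replace(c, score=float(scorer(c))) for c in candidates]


def select_top_k(candidates: Sequence[LoopCandidate], k: int) -> list[LoopCandidate]:
    """The k lowest-scoring (most conformationally stable) candidates.

    Output is sorted ascending by (score, sequence); ties at the cutoff are
    broken lexicographically by sequence so selection is deterministic.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    unscored = [c.sequence for c in candidates if c.score is None]
    if unscored:
        raise ValueError(f"{len(unscored)} unscored candidates (first: {unscored[0]})")
    if k > len(candidates):
        warnings.warn(
            f"k={k} exceeds candidate count {len(candidates)}; returning all",
            stacklevel=2,
        )
        k = len(candidates)
    return sorted(candidates, key=lambda c: (c.score, c.sequence))[:k]


def splice_combinations(
    top1: Sequence[LoopCandidate], top2: Sequence[LoopCandidate]
) -> SpliceSet:
    """Full Cartesian product of two junctions' shortlists (outer = junction 1)."""
    if not top1 or not top2:
        raise ValueError("both candidate lists must be non-empty")
    return SpliceSet(pairs=tuple((a, b) for a in top1 for b in top2))


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def write_candidates_tsv(candidates: Iterable[LoopCandidate], path: str | Path) -> None:
    lines = ["junction\tsequence\tscore"]
    for c in candidates:
        score = "" if c.score is None else f"{c.score:.6g}"
        lines.append(f"{c.junction}\t{c.sequence}\t{score}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_candidates_tsv(path: str | Path) -> list[LoopCandidate]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("junction\t") or line.startswith("#"):
            continue
        junction, sequence, *rest = line.split("\t")
        score = float(rest[0]) if rest and rest[0] else None
        out.append(LoopCandidate(junction, sequence, score))
    return out


def write_spliced_fasta(
    splices: SpliceSet, template: str, path: str | Path
) -> None:
    """Write full-length spliced designs as FASTA.

    ``template`` is the scaffold sequence with ``{loop1}`` and ``{loop2}``
    placeholders marking the two junctions.
    """
    if "{loop1}" not in template or "{loop2}" not in template:
        raise ValueError("template must contain {loop1} and {loop2} placeholders")
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for i, (c1, c2) in enumerate(splices.pairs, start=1):
        seq = template.replace("{loop1}", c1.sequence).replace("{loop2}", c2.sequence)
        records.append(
            SeqRecord(Seq(seq), id=f"splice_{i:04d}_{c1.sequence}_{c2.sequence}", description="")
        )
    seqio_write(records, str(path), "fasta")
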