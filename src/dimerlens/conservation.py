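"""Chemical-class sequence conservation over residue subsets of an MSA.

Residues are grouped into six side-chain chemistry classes: aliphatic
(G, A, V, L, I); hydroxyl- or sulfur-containing (S, C, T, M); cyclic (P);
aromatic (F, Y, W); basic (H, K, R); acidic and their amides (D, E, N, Q).
A column is *identical* when every sequence carries the same residue and
*conserved* when all residues fall in one chemical class; gap-containing
columns are neither.  Percent identity / conservation are reported over
arbitrary named column subsets (e.g. one helix, or its outward-facing
residues).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import AlignIO

from dimerlens.errors import AnalysisError

#: the six side-chain chemistry classes
CHEMICAL_CLASSES: dict[str, str] = {}
for _cls, _letters in {
    "aliphatic": "GAVLI",
    "hydroxyl_or_sulfur": "SCTM",
    "cyclic": "P",
    "aromatic": "FYW",
    "basic": "HKR",
    "acidic_and_amides": "DENQ",
}.items():
    for _x in _letters:
        CHEMICAL_CLASSES[_x] = _cls

GAP_CHARS = frozenset("-.")
GAP = "GAP"


def classify_residue(letter: str) -> str:
    """Chemical class of a one-letter residue code; gaps return the GAP sentinel."""
    letter = letter.upper()
    if letter in GAP_CHARS:
        return GAP
    try:
        return CHEMICAL_CLASSES[letter]
    except KeyError:
        raise AnalysisError(f"unclassified residue {letter!r}") from None


def column_metrics(column: str) -> tuple[bool, bool]:
    """(identical, conserved) flags for one alignment column.

    Identical: all residues equal.  Conserved: all residues share one
    chemical class.  Any gap makes the column neither.
    """
    if not column:
        raise AnalysisError("empty column")
    column = column.upper()
    classes = [classify_residue(x) for x in column]
    if GAP in classes:
        return False, False
    identical = len(set(column)) == 1
    conserved = len(set(classes)) == 1
    return identical, conserved


@dataclass
class ConservationStats:
    subset_name: str
    n_columns: int
    percent_conservation: float
    percent_identity: float
    column_flags: list[tuple[int, bool, bool]]  # (column index, identical, conserved)


@dataclass
class AlignmentView:
    """Aligned sequences with named column subsets (0-based indices)."""

    ids: list[str]
    sequences: list[str]
    subsets: dict[str, list[int]]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AnalysisError("empty alignment")
        self.sequences = [s.upper() for s in self.sequences]
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise AnalysisError("aligned sequences must have equal length")
        for name, idx in self.subsets.items():
            if any(not 0 <= i < L for i in idx):
                raise AnalysisError(f"subset {name!r} has out-of-bounds columns")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    def column(self, i: int) -> str:
        return "".join(s[i] for s in self.sequences)


def load_alignment(
    path,
    fmt: str = "fasta",
    subsets: dict[str, list[int]] | None = None,
) -> AlignmentView:
    """Read an aligned FASTA or Clustal file into an :class:`AlignmentView`."""
    aln = AlignIO.read(str(path), fmt)
    return AlignmentView(
        ids=[rec.id for rec in aln],
        sequences=[str(rec.seq) for rec in aln],
        subsets=subsets or {},
    )


def columns_from_reference(
    alignment: AlignmentView,
    reference_id: str,
    residue_numbers: list[int],
) -> list[int]:
    """Map 1-based residue numbers of an ungapped reference sequence to
    alignment column indices."""
    try:
        ref = alignment.sequences[alignment.ids.index(reference_id)]
    except ValueError:
        raise AnalysisError(f"reference sequence {reference_id!r} not in alignment") from None
    pos_to_col: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(ref):
        if ch not in GAP_CHARS:
            pos += 1
            pos_to_col[pos] = col
    out = []
    for num in residue_numbers:
        if num not in pos_to_col:
            raise AnalysisError(f"residue number {num} beyond reference length")
        out.append(pos_to_col[num])
    return out


def subset_stats(alignment: AlignmentView, subset: str | list[int]) -> ConservationStats:
    """Percent conservation and identity over a named or explicit column subset."""
    if isinstance(subset, str):
        if subset not in alignment.subsets:
            raise AnalysisError(f"unknown subset {subset!r}")
        name, columns = subset, alignment.subsets[subset]
    else:
        name, columns = "custom", list(subset)
    if not columns:
        raise AnalysisError("empty subset")
    flags = []
    for i in columns:
        identical, conserved = column_metrics(alignment.column(i))
        flags.append((i, identical, conserved))
    n = len(flags)
    return ConservationStats(
        subset_name=name,
        n_columns=n,
        percent_conservation=sum(c for _, _, c in flags) / n * 100.0,
        percent_identity=sum(i for _, i, _ in flags) / n * 100.0,
        column_flags=flags,
    )
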