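"""Per-column conservation statistics over a homolog alignment.

Columns are summarized by residue frequencies, physico-chemical class
fractions, gap fraction, and information content.  Class fractions use fixed
(configurable) class sets — nonpolar {A,V,L,I,M,F,W,P,G}, acidic {D,E}, basic
{K,R} — and gaps count in the denominator, so a heavily gapped column can
never be called conserved.  A column is flagged conserved when a single class
fraction strictly exceeds the threshold (default 0.80).

Information content is log2(20) minus the Shannon entropy of the non-gap
residue distribution (no small-sample correction), i.e. 4.32 bits for an
invariant column and 0 for a uniform one.

Columns are mapped to native numbering on a chosen reference sequence by
skipping the reference row's gaps.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

from Bio import SeqIO

from .errors import AlignmentError

__all__ = [
    "MSA",
    "ColumnStats",
    "DEFAULT_CLASSES",
    "read_alignment",
    "column_stats",
    "flag_conserved",
    "consensus",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = frozenset("-.")

DEFAULT_CLASSES: dict[str, frozenset[str]] = {
    "nonpolar": frozenset("AVLIMFWPG"),
    "acidic": frozenset("DE"),
    "basic": frozenset("KR"),
}


@dataclasses.dataclass
class MSA:
    sequences: list[tuple[str, str]]  # (id, aligned sequence)

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise AlignmentError("alignment needs at least 2 sequences")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        ids = [sid for sid, _ in self.sequences]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise AlignmentError(f"duplicate sequence id {dup!r}")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0][1])

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def column(self, idx: int) -> str:
        return "".join(seq[idx] for _, seq in self.sequences)


@dataclasses.dataclass
class ColumnStats:
    column: int  # 0-based alignment column
    native_num: int | None  # reference-sequence numbering; None at reference gaps
    frequencies: dict[str, float]  # residue -> count / n_sequences
    class_fractions: dict[str, float]  # includes "other"
    gap_fraction: float
    information: float  # bits


def read_alignment(path: str | Path) -> MSA:
    """Read an aligned FASTA file; lengths must match and ids must be unique."""
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise AlignmentError(f"{path.name}: {exc}") from exc
    if not records:
        raise AlignmentError(f"{path.name}: no sequences found")
    return MSA(sequences=[(r.id, str(r.seq).upper()) for r in records])


def write_alignment(msa: MSA, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in msa.sequences:
            fh.write(f">{sid}\n{seq}\n")


def column_stats(
    msa: MSA,
    reference_id: str,
    classes: dict[str, frozenset[str]] | None = None,
    reference_start: int = 1,
) -> list[ColumnStats]:
    """Per-column frequencies, class fractions, gap fraction and information.

    `reference_start` is the native number of the reference sequence's first
    non-gap position.
    """
    classes = classes or DEFAULT_CLASSES
    ref_seq = None
    for sid, seq in msa.sequences:
        if sid == reference_id:
            ref_seq = seq
            break
    if ref_seq is None:
        raise AlignmentError(f"reference id {reference_id!r} not in alignment")

    n = msa.n_sequences
    stats = []
    native = reference_start - 1
    for col_idx in range(msa.n_columns):
        col = msa.column(col_idx)
        ref_is_gap = ref_seq[col_idx] in GAP_CHARS
        if not ref_is_gap:
            native += 1
        counts: dict[str, int] = {}
        gaps = 0
        for ch in col:
            if ch in GAP_CHARS:
                gaps += 1
            else:
                counts[ch] = counts.get(ch, 0) + 1
        frequencies = {aa: c / n for aa, c in sorted(counts.items())}
        gap_fraction = gaps / n

        class_fractions = {}
        assigned: set[str] = set()
        for cname, members in classes.items():
            class_fractions[cname] = sum(c for aa, c in counts.items() if aa in members) / n
            assigned |= members
        class_fractions["other"] = sum(
            c for aa, c in counts.items() if aa not in assigned
        ) / n

        non_gap = n - gaps
        if non_gap > 0:
            entropy = -sum(
                (c / non_gap) * math.log2(c / non_gap) for c in counts.values()
            )
            information = math.log2(20) - entropy
        else:
            information = 0.0
        stats.append(
            ColumnStats(
                column=col_idx,
                native_num=None if ref_is_gap else native,
                frequencies=frequencies,
                class_fractions=class_fractions,
                gap_fraction=gap_fraction,
                information=max(0.0, information),
            )
        )
    return stats


def flag_conserved(
    stats: list[ColumnStats],
    threshold: float = 0.80,
    mode: str = "class",
) -> list[tuple[int | None, str]]:
    """Columns where a single class (or residue) fraction strictly exceeds the threshold.

    Returns ``(native_num, class_name)`` pairs; in ``mode="residue"`` the class
    name is the conserved residue itself.  The inequality is strict: a
    fraction exactly at the threshold is not flagged.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    flagged = []
    for st in stats:
        if mode == "class":
            candidates = {k: v for k, v in st.class_fractions.items() if k != "other"}
        elif mode == "residue":
            candidates = st.frequencies
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if not candidates:
            continue
        best = max(candidates, key=lambda k: (candidates[k], k))
        if candidates[best] > threshold:
            flagged.append((st.native_num, best))
    return flagged


def consensus(msa: MSA) -> str:
    """Majority-rule consensus: most frequent non-gap residue per column.

    Ties break alphabetically; columns with gap fraction > 0.5 are emitted in
    lowercase.  All-gap columns yield '-'.
    """
    out = []
    n = msa.n_sequences
    for col_idx in range(msa.n_columns):
        col = msa.column(col_idx)
        counts: dict[str, int] = {}
        gaps = 0
        for ch in col:
            if ch in GAP_CHARS:
                gaps += 1
            else:
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            out.append("-")
            continue
        best = min(counts, key=lambda aa: (-counts[aa], aa))
        out.append(best.lower() if gaps / n > 0.5 else best)
    return "".join(out)
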