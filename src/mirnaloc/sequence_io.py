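"""FASTA input, sequence validation and dinucleotide windowing.

Mature miRNAs are short (typically 18-25 nt) single-stranded RNAs.  Public
databases ship them in a mixture of RNA (U) and DNA (T) alphabets, so the
reader normalizes case and optionally maps T to U before validating against
the strict {A, C, G, U} alphabet every downstream encoder assumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: The eight compartments handled by the default predictor.
DEFAULT_LOCALIZATIONS = (
    "axon",
    "circulating",
    "cytoplasm",
    "exosome",
    "extracellular_vesicle",
    "microvesicle",
    "mitochondrion",
    "nucleus",
)


class SequenceError(ValueError):
    """Raised for invalid residues or degenerate (too-short) sequences."""


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence: identifier plus residues over {A, C, G, U}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains non-RNA residues: {sorted(bad)}"
            )
        if len(self.residues) < 2:
            raise SequenceError(
                f"sequence {self.id!r} has length {len(self.residues)} < 2; "
                "no dinucleotide exists"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


def _normalize(raw: str, policy: str, seq_id: str) -> str | None:
    """Return normalized residues, or None when the record should be dropped."""
    s = raw.upper()
    if policy == "convert_t":
        s = s.replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        if policy == "skip_invalid":
            logger.warning(
                "dropping sequence %r: invalid residues %s", seq_id, sorted(bad)
            )
            return None
        raise SequenceError(
            f"sequence {seq_id!r} contains invalid residues {sorted(bad)} "
            f"under policy {policy!r}"
        )
    return s


def read_fasta(path: str | Path, alphabet_policy: str = "convert_t") -> list[RnaSequence]:
    """Read RNA sequences from a FASTA file.

    Parameters
    ----------
    path
        FASTA file (multi-record, wrapped or single-line).
    alphabet_policy
        ``"strict"`` raises on any residue outside {A, C, G, U};
        ``"convert_t"`` (default) maps T to U first, matching the mixed
        DNA/RNA conventions of miRNA databases; ``"skip_invalid"`` drops
        offending records with a logged warning.

    Returns
    -------
    list of :class:`RnaSequence` in file order.
    """
    if alphabet_policy not in ("strict", "convert_t", "skip_invalid"):
        raise ValueError(f"unknown alphabet_policy {alphabet_policy!r}")
    out: list[RnaSequence] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        residues = _normalize(str(record.seq), alphabet_policy, record.id)
        if residues is None:
            continue
        if record.id in seen:
            raise SequenceError(f"duplicate sequence id {record.id!r} in {path}")
        seen.add(record.id)
        out.append(RnaSequence(id=record.id, residues=residues))
    return out


def write_fasta(seqs: Iterable[RnaSequence], path: str | Path) -> None:
    """Write sequences as single-line FASTA records."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def dinucleotides(seq: RnaSequence | str) -> list[str]:
    """Overlapping dinucleotide windows of a sequence, in order (length L-1)."""
    residues = seq.residues if isinstance(seq, RnaSequence) else seq
    if len(residues) < 2:
        raise SequenceError(f"sequence of length {len(residues)} has no dinucleotide")
    return [residues[i : i + 2] for i in range(len(residues) - 1)]


@dataclass(frozen=True)
class LabelTable:
    """Mapping sequence id -> set of localization names (multi-label)."""

    labels: Mapping[str, frozenset[str]]
    localizations: tuple[str, ...] = field(default=DEFAULT_LOCALIZATIONS)

    def __post_init__(self) -> None:
        allowed = set(self.localizations)
        for sid, locs in self.labels.items():
            if not locs:
                raise ValueError(f"sequence {sid!r} carries no label")
            unknown = set(locs) - allowed
            if unknown:
                raise ValueError(
                    f"sequence {sid!r} has unknown localization(s) {sorted(unknown)}; "
                    f"configured list: {list(self.localizations)}"
                )

    def __getitem__(self, sid: str) -> frozenset[str]:
        return self.labels[sid]

    def __contains__(self, sid: str) -> bool:
        return sid in self.labels

    def ids(self) -> list[str]:
        return list(self.labels)

    def positives(self, localization: str) -> set[str]:
        """Ids labelled with `localization`."""
        if localization not in self.localizations:
            raise KeyError(f"unknown localization {localization!r}")
        return {sid for sid, locs in self.labels.items() if localization in locs}


def read_labels(
    path: str | Path, localizations: tuple[str, ...] = DEFAULT_LOCALIZATIONS
) -> LabelTable:
    """Read a two-column TSV (sequence_id <TAB> comma-separated localizations).

    A header row is required; duplicate ids are an error.
    """
    labels: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.strip() or "\t" not in header:
            raise ValueError(f"{path}: expected a tab-separated header row")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            sid, locs = parts
            if sid in labels:
                raise ValueError(f"{path}:{lineno}: duplicate sequence id {sid!r}")
            labels[sid] = frozenset(x.strip() for x in locs.split(",") if x.strip())
    return LabelTable(labels=labels, localizations=localizations)


def restrict_to_observed(table: LabelTable) -> LabelTable:
    """Drop configured localizations that no sequence carries (order kept)."""
    observed = set().union(*table.labels.values()) if table.labels else set()
    locs = tuple(loc for loc in table.localizations if loc in observed)
    return LabelTable(labels=table.labels, localizations=locs)


def write_labels(table: LabelTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\tlocalizations\n")
        for sid, locs in table.labels.items():
            fh.write(f"{sid}\t{','.join(sorted(locs))}\n")
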