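"""FASTA input/output and uridine-centered fragment handling.

The classification unit throughout this package is the *U-centered
fragment*: an odd-length RNA subsequence whose central residue is a
uridine, the candidate pseudouridylation site.  Public Ψ benchmark sets
(H_990, M_944, S_628 and the H_200/S_200 independent test sets) ship as
pairs of FASTA files — one of confirmed Ψ-site fragments, one of
confirmed non-sites — with a fixed fragment length per species: 21 nt
for *H. sapiens* and *M. musculus*, 31 nt for *S. cerevisiae*.  This
module reads and writes that layout and extracts sliding U-centered
windows from whole RNA sequences for scanning.

Coordinates: fragment-internal indices are 0-based (so the central U of
a 21-mer sits at index 10); positions reported against a parent
sequence are 1-based, as users expect from sequence viewers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
AMBIGUOUS_ALPHABET = frozenset("ACGUN")

#: Window length per shipped species profile: H. sapiens and M. musculus
#: fragments are 21 nt, S. cerevisiae fragments are 31 nt.
SPECIES_WINDOWS = {"H": 21, "M": 21, "S": 31}

AlphabetPolicy = Literal["strict", "allow_ambiguous", "dna_ok"]
EdgePolicy = Literal["skip", "pad"]

PAD_SYMBOL = "N"


class FastaFormatError(ValueError):
    """Raised when a file is not parseable as FASTA."""


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside the allowed alphabet."""


class FragmentError(ValueError):
    """Raised when fragments violate the U-centered fragment contract."""


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence with identifier and optional free-text description."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlphabetError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class UCenteredFragment:
    """Odd-length fragment with a central U.

    ``label`` is 1 for a confirmed Ψ site, 0 for a confirmed non-site and
    ``None`` for unlabeled fragments produced by scanning.  ``origin``
    records ``(parent sequence id, 1-based position of the central U)``.
    """

    residues: str
    label: Optional[int] = None
    origin: Optional[tuple[str, int]] = None

    def __post_init__(self) -> None:
        n = len(self.residues)
        if n < 3 or n % 2 == 0:
            raise FragmentError(
                f"fragment length must be odd and >= 3, got {n} ({self._name()})"
            )
        bad = set(self.residues) - AMBIGUOUS_ALPHABET
        if bad:
            raise FragmentError(
                f"fragment {self._name()} contains disallowed characters {sorted(bad)}"
            )
        if self.residues[self.center_index] != "U":
            raise FragmentError(
                f"fragment {self._name()} has {self.residues[self.center_index]!r} "
                f"at its center, expected 'U'"
            )
        if self.label not in (None, 0, 1):
            raise FragmentError(f"label must be 0, 1 or None, got {self.label!r}")

    def _name(self) -> str:
        return self.origin[0] if self.origin else "<anonymous>"

    @property
    def center_index(self) -> int:
        return (len(self.residues) - 1) // 2

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class FragmentDataset:
    """An ordered collection of equal-length U-centered fragments."""

    fragments: list[UCenteredFragment]
    species_tag: str = "custom"

    def __post_init__(self) -> None:
        lengths = {len(f) for f in self.fragments}
        if len(lengths) > 1:
            raise FragmentError(f"mixed fragment lengths in dataset: {sorted(lengths)}")

    @property
    def window_length(self) -> Optional[int]:
        return len(self.fragments[0]) if self.fragments else None

    @property
    def counts(self) -> tuple[int, int]:
        """(n_positive, n_negative) among labeled fragments."""
        pos = sum(1 for f in self.fragments if f.label == 1)
        neg = sum(1 for f in self.fragments if f.label == 0)
        return pos, neg

    def labels(self) -> list[Optional[int]]:
        return [f.label for f in self.fragments]

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self) -> Iterator[UCenteredFragment]:
        return iter(self.fragments)

    def __getitem__(self, i):
        return self.fragments[i]


def _validate_residues(seq_id: str, residues: str, alphabet: frozenset) -> None:
    for offset, ch in enumerate(residues, start=1):
        if ch not in alphabet:
            raise AlphabetError(
                f"sequence {seq_id!r}: disallowed character {ch!r} at offset {offset}"
            )


def read_fasta(path, alphabet_policy: AlphabetPolicy = "strict") -> list[RnaSequence]:
    """Read a FASTA file into :class:`RnaSequence` records, order preserved.

    Policies: ``strict`` admits only A/C/G/U after uppercasing;
    ``allow_ambiguous`` additionally admits N; ``dna_ok`` transliterates
    T to U before strict validation (public Ψ benchmarks circulate in
    the DNA alphabet).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaFormatError(
                        f"{path}: line {lineno} is not a FASTA header; "
                        "expected a line starting with '>'"
                    )
                break
    if alphabet_policy not in ("strict", "allow_ambiguous", "dna_ok"):
        raise ValueError(f"unknown alphabet policy {alphabet_policy!r}")
    alphabet = AMBIGUOUS_ALPHABET if alphabet_policy == "allow_ambiguous" else RNA_ALPHABET

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        if alphabet_policy == "dna_ok":
            residues = residues.replace("T", "U")
        _validate_residues(rec.id, residues, alphabet)
        records.append(RnaSequence(id=rec.id, residues=residues,
                                   description=rec.description))
    return records


def write_fasta(sequences: Iterable[RnaSequence], path, width: int = 70) -> None:
    """Write records to FASTA, wrapping at ``width`` columns."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id,
                  description=s.description if s.description != s.id else "")
        for s in sequences
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def extract_u_windows(
    seq: RnaSequence, window_length: int, edge_policy: EdgePolicy = "skip"
) -> list[UCenteredFragment]:
    """Extract one unlabeled U-centered window per uridine in ``seq``.

    With ``skip`` (default) only uridines whose full window fits inside
    the sequence yield a fragment; with ``pad`` every uridine yields one,
    out-of-range flanks filled with ``N`` (which downstream encodes to
    all-zero chemical-property flags).  Fragments are ordered by the
    1-based position of their central U, recorded in ``origin``.
    """
    if window_length < 3 or window_length % 2 == 0:
        raise ValueError(f"window_length must be odd and >= 3, got {window_length}")
    if edge_policy not in ("skip", "pad"):
        raise ValueError(f"unknown edge policy {edge_policy!r}")
    flank = (window_length - 1) // 2
    residues = seq.residues
    out = []
    for i, ch in enumerate(residues):
        if ch != "U":
            continue
        lo, hi = i - flank, i + flank + 1
        if edge_policy == "skip":
            if lo < 0 or hi > len(residues):
                continue
            window = residues[lo:hi]
        else:
            left_pad = max(0, -lo)
            right_pad = max(0, hi - len(residues))
            window = (PAD_SYMBOL * left_pad
                      + residues[max(lo, 0):min(hi, len(residues))]
                      + PAD_SYMBOL * right_pad)
        out.append(UCenteredFragment(residues=window, origin=(seq.id, i + 1)))
    return out


def _fragments_from_records(
    records: Sequence[RnaSequence], label: Optional[int]
) -> tuple[list[UCenteredFragment], list[str]]:
    fragments, bad_ids = [], []
    for rec in records:
        try:
            fragments.append(
                UCenteredFragment(residues=rec.residues, label=label,
                                  origin=(rec.id, (len(rec.residues) + 1) // 2))
            )
        except FragmentError:
            bad_ids.append(rec.id)
    return fragments, bad_ids


def load_fragment_pair(
    positives_path,
    negatives_path,
    species_tag: str = "custom",
    alphabet_policy: AlphabetPolicy = "dna_ok",
) -> FragmentDataset:
    """Load a labeled dataset from a (positives, negatives) FASTA pair."""
    pos_records = read_fasta(positives_path, alphabet_policy)
    neg_records = read_fasta(negatives_path, alphabet_policy)
    if not pos_records:
        logger.warning("positives file %s contains no sequences", positives_path)
    if not neg_records:
        logger.warning("negatives file %s contains no sequences", negatives_path)
    pos, bad_pos = _fragments_from_records(pos_records, 1)
    neg, bad_neg = _fragments_from_records(neg_records, 0)
    if bad_pos or bad_neg:
        raise FragmentError(
            "records violating the central-U fragment contract: "
            f"{bad_pos + bad_neg}"
        )
    return FragmentDataset(fragments=pos + neg, species_tag=species_tag)


def load_fragment_dataset(
    path,
    label_convention: Literal["fasta_pair", "header_tag"] = "fasta_pair",
    alphabet_policy: AlphabetPolicy = "dna_ok",
) -> FragmentDataset:
    """Load a labeled fragment dataset described by a JSON manifest.

    With ``fasta_pair`` the manifest names ``positives`` and
    ``negatives`` FASTA paths (relative paths resolved against the
    manifest).  With ``header_tag`` it names a single ``sequences``
    FASTA whose record ids end in ``|1`` (positive) or ``|0``
    (negative).  Optional keys: ``species_tag``, ``window_length``
    (checked against the data when present).
    """
    path = Path(path)
    manifest = json.loads(path.read_text())
    species_tag = manifest.get("species_tag", "custom")

    if label_convention == "fasta_pair":
        dataset = load_fragment_pair(
            path.parent / manifest["positives"],
            path.parent / manifest["negatives"],
            species_tag=species_tag,
            alphabet_policy=alphabet_policy,
        )
    elif label_convention == "header_tag":
        records = read_fasta(path.parent / manifest["sequences"], alphabet_policy)
        fragments, bad = [], []
        for rec in records:
            base, _, tag = rec.id.rpartition("|")
            if tag not in ("0", "1") or not base:
                bad.append(rec.id)
                continue
            try:
                fragments.append(
                    UCenteredFragment(residues=rec.residues, label=int(tag),
                                      origin=(base, (len(rec.residues) + 1) // 2))
                )
            except FragmentError:
                bad.append(rec.id)
        if bad:
            raise FragmentError(f"records with missing labels or non-central U: {bad}")
        dataset = FragmentDataset(fragments=fragments, species_tag=species_tag)
    else:
        raise ValueError(f"unknown label convention {label_convention!r}")

    declared = manifest.get("window_length")
    if declared is not None and dataset.window_length not in (None, declared):
        raise FragmentError(
            f"manifest declares window_length={declared} but data has "
            f"{dataset.window_length}"
        )
    return dataset


def write_dataset(dataset: FragmentDataset, directory, stem: str = "dataset") -> Path:
    """Write a labeled dataset as a FASTA pair plus JSON manifest.

    Returns the manifest path.  The layout round-trips through
    :func:`load_fragment_dataset`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def as_records(label: int, prefix: str) -> list[RnaSequence]:
        return [
            RnaSequence(id=f.origin[0] if f.origin else f"{prefix}{i:05d}",
                        residues=f.residues)
            for i, f in enumerate(dataset.fragments)
            if f.label == label
        ]

    pos_path = directory / f"{stem}_positives.fasta"
    neg_path = directory / f"{stem}_negatives.fasta"
    write_fasta(as_records(1, "pos"), pos_path)
    write_fasta(as_records(0, "neg"), neg_path)
    n_pos, n_neg = dataset.counts
    manifest = {
        "positives": pos_path.name,
        "negatives": neg_path.name,
        "species_tag": dataset.species_tag,
        "window_length": dataset.window_length,
        "n_positive": n_pos,
        "n_negative": n_neg,
    }
    manifest_path = directory / f"{stem}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest_path
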