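"""Sequence-to-feature encoders: NCP, CKSNAP and PseKNC.

NCP (nucleotide chemical properties) is the primary scheme: each
nucleotide maps to three binary flags describing its chemistry —

=================  =========  ==========
property           flag = 1   flag = 0
=================  =========  ==========
ring structure     purine     pyrimidine
functional group   amino      keto
hydrogen bonding   weak       strong
=================  =========  ==========

giving A=[1,1,1], C=[0,1,0], G=[1,0,0], U=[0,0,1].  No two nucleotides
share more than one flag, so every pair of codes differs in exactly two
of the three positions.  A fragment of length n encodes to a 3n-vector
with position i (0-based) occupying slots 3i..3i+2 in (ring,
functional, hydrogen-bond) order; a 21-mer thus yields 63 features and
a 31-mer 93.  The pad/ambiguity symbol N encodes as [0,0,0].

CKSNAP (composition of k-spaced nucleic acid pairs) and PseKNC
(pseudo-k-tuple nucleotide composition, Type I) are comparison schemes.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .sequence_io import FragmentDataset, UCenteredFragment

NUCLEOTIDES = ("A", "C", "G", "U")

NCP_PROPERTIES = ("ring", "functional", "hbond")

#: Chemical-property flags per nucleotide, (ring, functional, hbond).
NCP_CODE: Mapping[str, tuple[int, int, int]] = {
    "A": (1, 1, 1),
    "C": (0, 1, 0),
    "G": (1, 0, 0),
    "U": (0, 0, 1),
    "N": (0, 0, 0),
}

#: A-form RNA dinucleotide helical parameters (rise in Å, roll/tilt/twist
#: in degrees, shift/slide in Å), the property set conventionally used
#: for RNA PseKNC correlation factors.  Values are standardized per
#: property before use, so only their relative spacing matters.
RNA_DINUC_PROPERTIES: Mapping[str, Mapping[str, float]] = {
    "rise": {
        "AA": 3.18, "AC": 3.24, "AG": 3.30, "AU": 3.24,
        "CA": 3.45, "CC": 3.36, "CG": 3.20, "CU": 3.30,
        "GA": 3.38, "GC": 3.32, "GG": 3.36, "GU": 3.24,
        "UA": 3.26, "UC": 3.38, "UG": 3.45, "UU": 3.18,
    },
    "roll": {
        "AA": 7.0, "AC": 4.8, "AG": 8.5, "AU": 7.1,
        "CA": 9.9, "CC": 8.7, "CG": 12.1, "CU": 8.5,
        "GA": 9.4, "GC": 6.1, "GG": 8.7, "GU": 4.8,
        "UA": 10.7, "UC": 9.4, "UG": 9.9, "UU": 7.0,
    },
    "shift": {
        "AA": -0.08, "AC": 0.23, "AG": -0.04, "AU": -0.06,
        "CA": 0.11, "CC": -0.01, "CG": 0.30, "CU": -0.04,
        "GA": 0.07, "GC": 0.07, "GG": -0.01, "GU": 0.23,
        "UA": -0.02, "UC": 0.07, "UG": 0.11, "UU": -0.08,
    },
    "slide": {
        "AA": -1.27, "AC": -1.43, "AG": -1.50, "AU": -1.36,
        "CA": -1.46, "CC": -1.78, "CG": -1.89, "CU": -1.50,
        "GA": -1.70, "GC": -1.39, "GG": -1.78, "GU": -1.43,
        "UA": -1.45, "UC": -1.70, "UG": -1.46, "UU": -1.27,
    },
    "tilt": {
        "AA": -0.8, "AC": 0.8, "AG": 0.5, "AU": 1.1,
        "CA": 1.0, "CC": 0.3, "CG": -0.1, "CU": 0.5,
        "GA": 1.3, "GC": 0.0, "GG": 0.3, "GU": 0.8,
        "UA": -0.2, "UC": 1.3, "UG": 1.0, "UU": -0.8,
    },
    "twist": {
        "AA": 31.0, "AC": 32.0, "AG": 30.0, "AU": 33.0,
        "CA": 31.0, "CC": 32.0, "CG": 27.0, "CU": 30.0,
        "GA": 32.0, "GC": 35.0, "GG": 32.0, "GU": 32.0,
        "UA": 32.0, "UC": 32.0, "UG": 31.0, "UU": 31.0,
    },
}


class EncodingError(ValueError):
    """Raised when a fragment cannot be encoded under the chosen scheme."""


def _residues(fragment: Union[UCenteredFragment, str]) -> str:
    return fragment.residues if isinstance(fragment, UCenteredFragment) else fragment


# ---------------------------------------------------------------------------
# NCP

def ncp_feature_names(n: int) -> list[str]:
    """Feature labels for an n-nt fragment; index 3i+j is pos{i}_{property j}."""
    return [f"pos{i}_{prop}" for i in range(n) for prop in NCP_PROPERTIES]


def encode_ncp(
    fragment: Union[UCenteredFragment, str], allow_n: bool = True
) -> np.ndarray:
    """Encode a fragment as its 3n-vector of chemical-property flags."""
    residues = _residues(fragment)
    allowed = set(NUCLEOTIDES) | ({"N"} if allow_n else set())
    out = np.empty(3 * len(residues), dtype=float)
    for i, ch in enumerate(residues):
        if ch not in allowed:
            raise EncodingError(
                f"cannot NCP-encode character {ch!r} at position {i} (0-based)"
            )
        out[3 * i: 3 * i + 3] = NCP_CODE[ch]
    return out


# ---------------------------------------------------------------------------
# CKSNAP

def cksnap_feature_names(k_max: int) -> list[str]:
    return [
        f"g{g}_{x}{y}"
        for g in range(k_max + 1)
        for x, y in itertools.product(NUCLEOTIDES, repeat=2)
    ]


def encode_cksnap(
    fragment: Union[UCenteredFragment, str], k_max: int = 5
) -> np.ndarray:
    """Composition of k-spaced nucleotide pairs for gaps 0..k_max.

    For gap g, the feature for ordered pair (x, y) is the count of
    positions i holding x with y at i+g+1, divided by the number of
    such positions.  Pairs involving N are excluded from both the count
    and the denominator, so each gap block still sums to 1 whenever at
    least one N-free pair exists.
    """
    residues = _residues(fragment)
    n = len(residues)
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    if n <= k_max + 1:
        raise ValueError(
            f"fragment of length {n} too short for gap {k_max} "
            f"(needs length > {k_max + 1})"
        )
    pair_index = {
        x + y: j for j, (x, y) in enumerate(itertools.product(NUCLEOTIDES, repeat=2))
    }
    out = np.zeros(16 * (k_max + 1), dtype=float)
    for g in range(k_max + 1):
        counts = np.zeros(16)
        valid = 0
        for i in range(n - g - 1):
            pair = residues[i] + residues[i + g + 1]
            if pair in pair_index:
                counts[pair_index[pair]] += 1
                valid += 1
        if valid:
            out[16 * g: 16 * (g + 1)] = counts / valid
    return out


# ---------------------------------------------------------------------------
# PseKNC (Type I)

@dataclass(frozen=True)
class PsekncParams:
    """Parameters of Type-I pseudo-k-tuple nucleotide composition.

    ``k`` is the tuple size (4**k composition features), ``lam`` the
    number of sequence-order correlation tiers, ``w`` their weight in
    [0, 1].  ``property_table`` maps property name → dinucleotide →
    value; it is standardized to zero mean and unit variance per
    property before computing correlation factors.
    """

    k: int = 2
    lam: int = 2
    w: float = 0.5
    property_table: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: RNA_DINUC_PROPERTIES
    )

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        dinucs = {x + y for x, y in itertools.product(NUCLEOTIDES, repeat=2)}
        for name, table in self.property_table.items():
            if set(table) != dinucs:
                raise ValueError(f"property {name!r} must cover all 16 dinucleotides")


def _standardized_property_matrix(
    table: Mapping[str, Mapping[str, float]]
) -> dict[str, np.ndarray]:
    """dinucleotide → vector of z-scored property values."""
    dinucs = [x + y for x, y in itertools.product(NUCLEOTIDES, repeat=2)]
    matrix = np.array([[table[p][d] for d in dinucs] for p in table], dtype=float)
    mean = matrix.mean(axis=1, keepdims=True)
    std = matrix.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    z = (matrix - mean) / std
    return {d: z[:, j] for j, d in enumerate(dinucs)}


def pseknc_feature_names(params: PsekncParams) -> list[str]:
    kmers = ["".join(t) for t in itertools.product(NUCLEOTIDES, repeat=params.k)]
    return [f"f_{m}" for m in kmers] + [f"theta_{j}" for j in range(1, params.lam + 1)]


def encode_pseknc(
    fragment: Union[UCenteredFragment, str],
    params: Optional[PsekncParams] = None,
) -> np.ndarray:
    """Type-I PseKNC vector of length 4**k + lambda, summing to 1.

    The first 4**k entries are k-tuple frequencies damped by the
    w-weighted correlation mass; the last ``lam`` entries are the
    w-weighted tier-j factors θ_j, where θ_j averages the mean squared
    standardized-property distance between dinucleotides j positions
    apart.  k-tuples and dinucleotides containing N are skipped.
    """
    params = params or PsekncParams()
    params.validate()
    residues = _residues(fragment)
    n = len(residues)
    if params.lam >= n - 1:
        raise ValueError(
            f"lambda={params.lam} requires fragment length > {params.lam + 1}, got {n}"
        )
    if n < params.k:
        raise ValueError(f"fragment of length {n} too short for k={params.k}")

    kmers = ["".join(t) for t in itertools.product(NUCLEOTIDES, repeat=params.k)]
    kmer_index = {m: j for j, m in enumerate(kmers)}
    counts = np.zeros(len(kmers))
    for i in range(n - params.k + 1):
        mer = residues[i: i + params.k]
        if mer in kmer_index:
            counts[kmer_index[mer]] += 1
    if counts.sum() == 0:
        raise EncodingError("no valid k-tuples in fragment (all contain N)")
    freqs = counts / counts.sum()

    zprops = _standardized_property_matrix(params.property_table)
    thetas = np.zeros(params.lam)
    for j in range(1, params.lam + 1):
        dists, m = 0.0, 0
        for i in range(n - j - 1):
            d1 = residues[i: i + 2]
            d2 = residues[i + j: i + j + 2]
            if d1 in zprops and d2 in zprops:
                diff = zprops[d1] - zprops[d2]
                dists += float(np.mean(diff ** 2))
                m += 1
        thetas[j - 1] = dists / m if m else 0.0

    denom = 1.0 + params.w * thetas.sum()
    return np.concatenate([freqs, params.w * thetas]) / denom


# ---------------------------------------------------------------------------
# Dataset-level encoding

@dataclass
class FeatureMatrix:
    """samples × named features, rows aligned with the source fragments.

    Labels, when present, travel in the separate ``labels`` array —
    never as a column of ``values``.
    """

    values: np.ndarray
    feature_names: list[str]
    encoder_id: str
    params: dict = field(default_factory=dict)
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ValueError("values shape inconsistent with feature_names")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")
        if self.labels is not None and len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length does not match number of rows")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)

    def to_tsv(self, path) -> None:
        """Write values as TSV with a header row; parameters go to a
        JSON sidecar ``<path>.json`` (labels included when present)."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, sep="\t", index=False)
        sidecar = {"encoder_id": self.encoder_id, "params": self.params}
        if self.labels is not None:
            sidecar["labels"] = [int(v) for v in self.labels]
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t")
        sidecar_path = Path(str(path) + ".json")
        encoder_id, params, labels = "unknown", {}, None
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            encoder_id = sidecar.get("encoder_id", "unknown")
            params = sidecar.get("params", {})
            if "labels" in sidecar:
                labels = np.array(sidecar["labels"], dtype=int)
        return cls(values=frame.to_numpy(dtype=float),
                   feature_names=list(frame.columns),
                   encoder_id=encoder_id, params=params, labels=labels)


ENCODER_IDS = ("NCP", "CKSNAP", "PseKNC")


def encode_dataset(
    dataset: FragmentDataset,
    encoder_id: str = "NCP",
    k_max: int = 5,
    pseknc_params: Optional[PsekncParams] = None,
    window_length: Optional[int] = None,
) -> FeatureMatrix:
    """Encode every fragment; row i corresponds to fragment i.

    Labels (when all fragments carry one) are returned in
    ``FeatureMatrix.labels``, aligned with the rows.  ``window_length``
    only needs to be given for an empty dataset, where NCP feature
    names cannot be inferred from the data.
    """
    encoder_id = encoder_id.upper() if encoder_id.upper() in ("NCP", "CKSNAP") else encoder_id
    window = dataset.window_length or window_length

    if encoder_id == "NCP":
        names = ncp_feature_names(window or 0)
        params: dict = {}
        encode = encode_ncp
    elif encoder_id == "CKSNAP":
        names = cksnap_feature_names(k_max)
        params = {"k_max": k_max}
        encode = lambda f: encode_cksnap(f, k_max=k_max)  # noqa: E731
    elif encoder_id in ("PseKNC", "PSEKNC"):
        encoder_id = "PseKNC"
        pseknc_params = pseknc_params or PsekncParams()
        names = pseknc_feature_names(pseknc_params)
        params = {"k": pseknc_params.k, "lambda": pseknc_params.lam,
                  "w": pseknc_params.w}
        encode = lambda f: encode_pseknc(f, pseknc_params)  # noqa: E731
    else:
        raise ValueError(f"unknown encoder {encoder_id!r}; expected one of {ENCODER_IDS}")

    rows = []
    for fragment in dataset:
        try:
            rows.append(encode(fragment))
        except (EncodingError, ValueError) as exc:
            name = fragment.origin[0] if fragment.origin else "<anonymous>"
            raise EncodingError(f"fragment {name!r}: {exc}") from exc

    values = np.array(rows, dtype=float) if rows else np.empty((0, len(names)))
    raw_labels = dataset.labels()
    labels = (np.array(raw_labels, dtype=int)
              if rows and all(l is not None for l in raw_labels) else None)
    return FeatureMatrix(values=values, feature_names=names,
                         encoder_id=encoder_id, params=params, labels=labels)
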