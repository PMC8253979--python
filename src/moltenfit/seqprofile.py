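"""Sequence-level disorder composition profiling.

Intrinsically disordered regions are depleted in bulky hydrophobic
(order-promoting) residues and enriched in small, polar and charged
(disorder-promoting) residues. The default partition of the 20-letter
alphabet follows the widely used composition scale:

* disorder-promoting: A, G, R, D, H, Q, K, S, E, P
* order-promoting:    W, F, Y, I, M, L, V, N, C, T

Proline — the canonical helix breaker — is additionally reported on its
own. The module also computes the sequence's average molecular mass and
its molar extinction coefficient at 280 nm, the two quantities needed to
turn an absorbance reading into a molar concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio import SeqIO
from Bio.SeqUtils import molecular_weight

from .errors import ParameterError, ValidationError

__all__ = [
    "STANDARD_AA",
    "DISORDER_PROMOTING",
    "ORDER_PROMOTING",
    "SequenceRecord",
    "CompositionProfile",
    "read_fasta",
    "classify_composition",
    "windowed_fraction",
    "average_mass",
    "extinction_coefficient",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
DISORDER_PROMOTING = frozenset("AGRDHQKSEP")
ORDER_PROMOTING = frozenset("WFYIMLVNCT")


@dataclass
class SequenceRecord:
    """A protein sequence with an identifier.

    In strict mode (the default) residues must come from the 20 standard
    one-letter codes; otherwise nonstandard letters are tolerated and
    flagged.
    """

    identifier: str
    residues: str
    strict: bool = True

    def __post_init__(self):
        self.residues = self.residues.upper().replace("*", "")
        if not self.residues:
            raise ValidationError("empty sequence")
        unknown = set(self.residues) - STANDARD_AA
        self.nonstandard = sorted(unknown)
        if unknown and self.strict:
            raise ValidationError(
                f"nonstandard residues in {self.identifier}: "
                f"{''.join(sorted(unknown))}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def subsequence(self, start: int, end: int) -> "SequenceRecord":
        """1-based inclusive slice (e.g. residues 1146–1912)."""
        if not 1 <= start <= end <= len(self.residues):
            raise ParameterError(
                f"coordinates {start}-{end} outside sequence of length "
                f"{len(self.residues)}"
            )
        return SequenceRecord(
            identifier=f"{self.identifier}/{start}-{end}",
            residues=self.residues[start - 1 : end],
            strict=self.strict,
        )


@dataclass
class CompositionProfile:
    """Residue-class composition summary of one sequence."""

    identifier: str
    length: int
    counts: dict
    disorder_promoting_fraction: float
    order_promoting_fraction: float
    proline_fraction: float
    window: Optional[int] = None
    windowed_series: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def percent(self, which: str) -> int:
        """Integer percent, rounded half up (68.5 → 69)."""
        frac = getattr(self, f"{which}_fraction")
        return int(math.floor(frac * 100.0 + 0.5))


def read_fasta(path, strict: bool = True) -> list:
    """Read all records of a FASTA file into :class:`SequenceRecord` s."""
    records = [
        SequenceRecord(identifier=rec.id, residues=str(rec.seq),
                       strict=strict)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValidationError(f"no FASTA records in {path}")
    return records


def classify_composition(seq: SequenceRecord,
                         disorder_set=DISORDER_PROMOTING,
                         order_set=ORDER_PROMOTING) -> CompositionProfile:
    """Residue-class fractions under a (injectable) two-class partition.

    With the default partition, disorder- and order-promoting fractions
    sum to 1 for any standard sequence.
    """
    if set(disorder_set) & set(order_set):
        raise ParameterError("class sets overlap; not a partition")
    n = len(seq)
    counts = {aa: seq.residues.count(aa) for aa in sorted(set(seq.residues))}
    dis = sum(c for aa, c in counts.items() if aa in disorder_set)
    order = sum(c for aa, c in counts.items() if aa in order_set)
    pro = counts.get("P", 0)
    return CompositionProfile(
        identifier=seq.identifier,
        length=n,
        counts=counts,
        disorder_promoting_fraction=dis / n,
        order_promoting_fraction=order / n,
        proline_fraction=pro / n,
    )


def windowed_fraction(seq: SequenceRecord, window: int,
                      residue_class=DISORDER_PROMOTING) -> np.ndarray:
    """Sliding-window fraction of a residue class.

    Returns a series of length ``len(seq) − window + 1``; entry i is the
    class fraction over residues i..i+window−1. Window must be odd and no
    longer than the sequence.
    """
    if window % 2 == 0:
        raise ParameterError("window must be odd")
    if window > len(seq):
        raise ParameterError("window longer than sequence")
    member = np.fromiter(
        (aa in residue_class for aa in seq.residues), dtype=float,
        count=len(seq),
    )
    kernel = np.ones(window) / window
    return np.convolve(member, kernel, mode="valid")


def average_mass(seq: SequenceRecord) -> float:
    """Average (not monoisotopic) molecular mass in kDa: the sum of
    standard average residue masses plus one water."""
    if seq.nonstandard:
        raise ValidationError(
            f"cannot compute mass with nonstandard residues: "
            f"{seq.nonstandard}"
        )
    da = molecular_weight(seq.residues, seq_type="protein",
                          monoisotopic=False)
    return da / 1000.0


def extinction_coefficient(seq: SequenceRecord,
                           cystine_pairs: int = 0) -> float:
    """Molar extinction coefficient at 280 nm, M⁻¹cm⁻¹:
    ε = 5500·nW + 1490·nY + 125·n_cystine.

    ``cystine_pairs`` defaults to 0 (fully reduced protein).
    """
    if cystine_pairs < 0:
        raise ParameterError("cystine_pairs must be >= 0")
    n_c = seq.residues.count("C")
    if cystine_pairs > n_c // 2:
        raise ParameterError(
            f"{cystine_pairs} cystine pairs impossible with {n_c} cysteines"
        )
    n_w = seq.residues.count("W")
    n_y = seq.residues.count("Y")
    return 5500.0 * n_w + 1490.0 * n_y + 125.0 * cystine_pairs
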