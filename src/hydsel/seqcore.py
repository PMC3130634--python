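"""Sequence-level domain model: coding sequences, point mutations and their
amino-acid consequences, and the charge-change taxonomy used throughout the
selection analysis.

A hydrogenase variant isolated by genetic selection is summarized as a set of
nucleotide point mutations against a parent coding sequence (CDS).  Every
downstream statistic (charge-change enrichment, truncation mapping) starts
from the classification performed here: translate the parent and mutated
codons with the standard genetic code, call each mutation silent, missense or
nonsense, and — for missense changes — record the charge of the original and
replacement residue (positive / negative / neutral).

Coordinates are 1-based and inclusive in all public interfaces, matching the
conventions of the mutant summary tables this module reads and writes.
"""

from __future__ import annotations

import enum
import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Standard genetic code (NCBI table 1), all 64 codons, stops as '*'.
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


# ---------------------------------------------------------------------------
# Coding sequences and point mutations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodingSequence:
    """A validated CDS: strictly ACGT, length a positive multiple of 3."""

    id: str
    nt: str
    description: str = ""

    def __post_init__(self) -> None:
        nt = self.nt
        if len(nt) < 3 or len(nt) % 3 != 0:
            raise ValidationError(
                f"CDS {self.id!r}: length {len(nt)} is not a positive multiple of 3"
            )
        bad = re.search(f"[^{BASES}]", nt)
        if bad is not None:
            raise ValidationError(
                f"CDS {self.id!r}: invalid character {bad.group()!r} at "
                f"position {bad.start() + 1} (alphabet is strictly ACGT)"
            )

    def __len__(self) -> int:
        return len(self.nt)

    @property
    def n_codons(self) -> int:
        return len(self.nt) // 3

    def codon(self, codon_index: int) -> str:
        """Codon at 1-based ``codon_index``."""
        if not 1 <= codon_index <= self.n_codons:
            raise ValidationError(
                f"codon index {codon_index} out of range 1..{self.n_codons}"
            )
        i = (codon_index - 1) * 3
        return self.nt[i : i + 3]

    def translate(self) -> str:
        """Translate all codons with the standard code; stops appear as '*'."""
        return str(Seq(self.nt).translate())

    @property
    def protein(self) -> str:
        """Residue string with a single trailing stop, if present, removed."""
        aa = self.translate()
        return aa[:-1] if aa.endswith("*") else aa

    def base_index_array(self) -> np.ndarray:
        """The sequence as an int array over 0..3 (A,C,G,T)."""
        return np.frombuffer(
            self.nt.encode().translate(_NT_TRANSLATION), dtype=np.uint8
        ).astype(np.int64)


_NT_TRANSLATION = bytes.maketrans(b"ACGT", bytes([0, 1, 2, 3]))

_MUTATION_TOKEN = re.compile(r"^([ACGT])(\d+)([ACGT])$")


@dataclass(frozen=True, order=True)
class PointMutation:
    """A single-nucleotide substitution, 1-based, e.g. ``A123G``."""

    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"mutation position {self.position} must be >= 1")
        for b, name in ((self.ref_base, "ref"), (self.alt_base, "alt")):
            if b not in BASES:
                raise ValidationError(f"{name} base {b!r} is not one of ACGT")
        if self.ref_base == self.alt_base:
            raise ValidationError(
                f"position {self.position}: ref and alt base are both {self.ref_base!r}"
            )

    def token(self) -> str:
        return f"{self.ref_base}{self.position}{self.alt_base}"

    @classmethod
    def from_token(cls, token: str) -> "PointMutation":
        m = _MUTATION_TOKEN.match(token.strip().upper())
        if m is None:
            raise ValidationError(f"malformed mutation token {token!r} (expect e.g. A123G)")
        return cls(position=int(m.group(2)), ref_base=m.group(1), alt_base=m.group(3))

    def validate_against(self, seq: CodingSequence) -> None:
        if self.position > len(seq):
            raise ValidationError(
                f"mutation {self.token()} beyond end of CDS {seq.id!r} (L={len(seq)})"
            )
        actual = seq.nt[self.position - 1]
        if actual != self.ref_base:
            raise ValidationError(
                f"mutation {self.token()}: CDS {seq.id!r} has {actual!r} at "
                f"position {self.position}, not {self.ref_base!r}"
            )


def apply_mutations(
    seq: CodingSequence, muts: Sequence[PointMutation]
) -> CodingSequence:
    """Return the CDS with every mutation applied.

    Mutations must be valid against ``seq`` and occupy distinct positions;
    the result differs from ``seq`` exactly at the mutated positions.
    """
    positions = [m.position for m in muts]
    if len(set(positions)) != len(positions):
        dup = sorted({p for p in positions if positions.count(p) > 1})
        raise ValidationError(f"duplicate mutation positions: {dup}")
    nt = list(seq.nt)
    for m in muts:
        m.validate_against(seq)
        nt[m.position - 1] = m.alt_base
    return CodingSequence(id=seq.id, nt="".join(nt), description=seq.description)


# ---------------------------------------------------------------------------
# Charge taxonomy
# ---------------------------------------------------------------------------


class Charge(enum.Enum):
    POS = "POS"
    NEG = "NEG"
    NEU = "NEU"


@dataclass(frozen=True)
class ChargeScheme:
    """A partition of the 20 standard residues into positive/negative/neutral.

    The default places lysine and arginine in the positive set, aspartate and
    glutamate in the negative set, and everything else — histidine included —
    in the neutral set.  Histidine's placement is configurable because its
    protonation state is ambiguous at physiological pH.
    """

    positive: frozenset[str]
    negative: frozenset[str]
    neutral: frozenset[str]

    def __post_init__(self) -> None:
        sets = (self.positive, self.negative, self.neutral)
        union = set().union(*sets)
        if union != set(AMINO_ACIDS) or sum(map(len, sets)) != 20:
            raise ValidationError(
                "charge scheme must partition the 20 standard amino acids "
                f"(got union {''.join(sorted(union))!r})"
            )

    @classmethod
    def default(cls, histidine_positive: bool = False) -> "ChargeScheme":
        pos = {"K", "R"} | ({"H"} if histidine_positive else set())
        neg = {"D", "E"}
        neu = set(AMINO_ACIDS) - pos - neg
        return cls(frozenset(pos), frozenset(neg), frozenset(neu))

    def charge_of(self, aa: str) -> Optional[Charge]:
        """Charge of a residue; None for '*' (stops carry no charge)."""
        if aa in self.positive:
            return Charge.POS
        if aa in self.negative:
            return Charge.NEG
        if aa in self.neutral:
            return Charge.NEU
        return None


@dataclass(frozen=True, order=True)
class ChargeChangeClass:
    """One of the nine (from, to) charge combinations for missense changes."""

    from_charge: Charge
    to_charge: Charge

    @property
    def label(self) -> str:
        return f"{self.from_charge.value}->{self.to_charge.value}"

    @classmethod
    def from_label(cls, label: str) -> "ChargeChangeClass":
        f, t = label.split("->")
        return cls(Charge(f), Charge(t))


#: The nine classes in a fixed order (row-major over POS, NEG, NEU).
CLASS_ORDER: tuple[ChargeChangeClass, ...] = tuple(
    ChargeChangeClass(f, t)
    for f, t in itertools.product((Charge.POS, Charge.NEG, Charge.NEU), repeat=2)
)
CLASS_CODE: dict[ChargeChangeClass, int] = {c: i for i, c in enumerate(CLASS_ORDER)}

# Integer codes used by the vectorized classifier; 0-8 are CLASS_ORDER.
CODE_NONSENSE = 9
CODE_SILENT = 10
CODE_STOP_LOSS = 11  # mutation in a stop codon yielding a sense codon
N_CODES = 12
CODE_LABELS: tuple[str, ...] = tuple(c.label for c in CLASS_ORDER) + (
    "nonsense",
    "silent",
    "stop_loss",
)


class Category(enum.Enum):
    SILENT = "SILENT"
    MISSENSE = "MISSENSE"
    NONSENSE = "NONSENSE"


@dataclass(frozen=True)
class AminoChange:
    """Amino-acid consequence of one nucleotide mutation."""

    codon_index: int
    ref_aa: str
    alt_aa: str
    category: Category
    charge_class: Optional[ChargeChangeClass] = None

    @property
    def code(self) -> int:
        if self.category is Category.SILENT:
            return CODE_SILENT
        if self.category is Category.NONSENSE:
            return CODE_NONSENSE
        if self.charge_class is None:
            return CODE_STOP_LOSS
        return CLASS_CODE[self.charge_class]


def _make_change(
    codon_index: int, ref_aa: str, alt_aa: str, scheme: ChargeScheme
) -> AminoChange:
    if ref_aa == alt_aa:
        cat = Category.SILENT
    elif alt_aa == "*":
        cat = Category.NONSENSE
    else:
        cat = Category.MISSENSE
    cls = None
    if cat is Category.MISSENSE:
        fc, tc = scheme.charge_of(ref_aa), scheme.charge_of(alt_aa)
        if fc is not None and tc is not None:
            cls = ChargeChangeClass(fc, tc)
        # ref_aa == '*' (stop loss) has no from-charge and receives no class
    return AminoChange(codon_index, ref_aa, alt_aa, cat, cls)


def classify_mutation(
    seq: CodingSequence, mut: PointMutation, scheme: Optional[ChargeScheme] = None
) -> AminoChange:
    """Classify a single mutation against ``seq`` (standard genetic code)."""
    scheme = scheme or ChargeScheme.default()
    mut.validate_against(seq)
    ci = (mut.position - 1) // 3
    codon = seq.codon(ci + 1)
    offset = (mut.position - 1) % 3
    alt_codon = codon[:offset] + mut.alt_base + codon[offset + 1 :]
    return _make_change(ci + 1, CODON_TABLE[codon], CODON_TABLE[alt_codon], scheme)


def classify_variant(
    seq: CodingSequence,
    muts: Sequence[PointMutation],
    scheme: Optional[ChargeScheme] = None,
) -> list[AminoChange]:
    """Classify every mutation of a variant.

    Each mutation's reference residue comes from the parent codon and its
    replacement residue from the fully mutated codon, so two substitutions in
    the same codon are both judged against the final translated product.
    """
    scheme = scheme or ChargeScheme.default()
    mutated = apply_mutations(seq, muts)
    out = []
    for m in muts:
        ci = (m.position - 1) // 3
        out.append(
            _make_change(
                ci + 1,
                CODON_TABLE[seq.codon(ci + 1)],
                CODON_TABLE[mutated.codon(ci + 1)],
                scheme,
            )
        )
    return out


def single_mutation_code_table(
    seq: CodingSequence, scheme: Optional[ChargeScheme] = None
) -> np.ndarray:
    """(L, 4) array of classification codes for every possible single mutation.

    Entry [p, b] is the code (0-8 charge class, 9 nonsense, 10 silent,
    11 stop-loss) of mutating 0-based position ``p`` to base ``BASES[b]``;
    entries where b equals the reference base are 255.  Valid only for
    mutations considered one at a time (no same-codon interactions).
    """
    scheme = scheme or ChargeScheme.default()
    L = len(seq)
    table = np.full((L, 4), 255, dtype=np.uint8)
    for ci in range(seq.n_codons):
        codon = seq.nt[ci * 3 : ci * 3 + 3]
        ref_aa = CODON_TABLE[codon]
        for offset in range(3):
            p = ci * 3 + offset
            for b in BASES:
                if b == codon[offset]:
                    continue
                alt_codon = codon[:offset] + b + codon[offset + 1 :]
                change = _make_change(ci + 1, ref_aa, CODON_TABLE[alt_codon], scheme)
                table[p, BASE_INDEX[b]] = change.code
    return table


# ---------------------------------------------------------------------------
# Variant records and charge-change counting
# ---------------------------------------------------------------------------


class ActivityClass(enum.Enum):
    FULL = "FULL"
    PARTIAL = "PARTIAL"
    NONE = "NONE"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class VariantRecord:
    """One selected variant: parent gene, point mutations, activity call."""

    variant_id: str
    parent_id: str
    mutations: tuple[PointMutation, ...]
    activity_class: ActivityClass = ActivityClass.UNKNOWN
    measured_activity: Optional[float] = None

    def __post_init__(self) -> None:
        muts = tuple(sorted(self.mutations, key=lambda m: m.position))
        positions = [m.position for m in muts]
        if len(set(positions)) != len(positions):
            raise ValidationError(
                f"variant {self.variant_id!r}: duplicate mutation positions"
            )
        object.__setattr__(self, "mutations", muts)
        if self.measured_activity is not None and self.measured_activity < 0:
            raise ValidationError(
                f"variant {self.variant_id!r}: negative measured activity"
            )


@dataclass
class ChargeChangeCounts:
    """Tally of mutation consequences across a set of variants.

    ``classes`` holds the nine missense charge-change classes; nonsense,
    silent and stop-loss mutations are tallied separately so that the grand
    total always equals the number of mutations counted (conservation).
    """

    classes: dict[ChargeChangeClass, int]
    nonsense: int = 0
    silent: int = 0
    stop_loss: int = 0
    parent_id: Optional[str] = None

    @property
    def total(self) -> int:
        return sum(self.classes.values()) + self.nonsense + self.silent + self.stop_loss

    @property
    def nonsilent(self) -> int:
        return self.total - self.silent

    def as_vector(self) -> np.ndarray:
        """Counts as a length-12 vector in CODE order."""
        v = np.zeros(N_CODES, dtype=np.int64)
        for cls, n in self.classes.items():
            v[CLASS_CODE[cls]] = n
        v[CODE_NONSENSE] = self.nonsense
        v[CODE_SILENT] = self.silent
        v[CODE_STOP_LOSS] = self.stop_loss
        return v

    @classmethod
    def from_changes(
        cls, changes: Iterable[AminoChange], parent_id: Optional[str] = None
    ) -> "ChargeChangeCounts":
        counts = {c: 0 for c in CLASS_ORDER}
        nonsense = silent = stop_loss = 0
        for ch in changes:
            code = ch.code
            if code == CODE_NONSENSE:
                nonsense += 1
            elif code == CODE_SILENT:
                silent += 1
            elif code == CODE_STOP_LOSS:
                stop_loss += 1
            else:
                counts[CLASS_ORDER[code]] += 1
        return cls(counts, nonsense, silent, stop_loss, parent_id)


def count_charge_changes(
    variants: Sequence[VariantRecord],
    parent: CodingSequence,
    scheme: Optional[ChargeScheme] = None,
) -> ChargeChangeCounts:
    """Pool and classify all mutations of ``variants`` against ``parent``."""
    scheme = scheme or ChargeScheme.default()
    changes: list[AminoChange] = []
    for v in variants:
        if v.parent_id != parent.id:
            raise ValidationError(
                f"variant {v.variant_id!r} references parent {v.parent_id!r}, "
                f"not {parent.id!r}"
            )
        changes.extend(classify_variant(parent, v.mutations, scheme))
    return ChargeChangeCounts.from_changes(changes, parent_id=parent.id)


# ---------------------------------------------------------------------------
# I/O: FASTA and variant tables
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[CodingSequence]:
    """Read CDS records from FASTA; sequences are upper-cased and validated."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        nt = str(rec.seq).upper()
        bad = re.search(f"[^{BASES}]", nt)
        if bad is not None:
            raise ValidationError(
                f"record {rec.id!r}: invalid character {bad.group()!r} at "
                f"position {bad.start() + 1}"
            )
        if len(nt) < 3 or len(nt) % 3 != 0:
            raise ValidationError(
                f"record {rec.id!r}: length {len(nt)} is not a positive multiple of 3"
            )
        out.append(CodingSequence(id=rec.id, nt=nt, description=rec.description))
    return out


def write_fasta(
    seqs: Iterable[CodingSequence], path: str | Path, wrap: int = 60
) -> None:
    records = [
        SeqRecord(Seq(s.nt), id=s.id, description=s.description) for s in seqs
    ]
    with open(path, "w") as fh:
        writer = FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


VARIANT_COLUMNS = (
    "variant_id",
    "parent_id",
    "mutations",
    "activity_class",
    "measured_activity",
)


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a tab-separated variant table (header row mandatory).

    Columns: variant_id, parent_id, mutations (semicolon-joined tokens like
    ``A123G``; empty for none), activity_class, measured_activity (blank for
    not measured).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(
            f"variant table {path}: missing columns {sorted(missing)}"
        )
    out = []
    for row in df.itertuples(index=False):
        tokens = [t for t in str(row.mutations).split(";") if t.strip()]
        muts = tuple(PointMutation.from_token(t) for t in tokens)
        activity = str(row.measured_activity).strip()
        out.append(
            VariantRecord(
                variant_id=str(row.variant_id),
                parent_id=str(row.parent_id),
                mutations=muts,
                activity_class=ActivityClass(str(row.activity_class).strip().upper()),
                measured_activity=float(activity) if activity else None,
            )
        )
    return out


def write_variant_table(variants: Iterable[VariantRecord], path: str | Path) -> None:
    rows = [
        {
            "variant_id": v.variant_id,
            "parent_id": v.parent_id,
            "mutations": ";".join(m.token() for m in v.mutations),
            "activity_class": v.activity_class.value,
            "measured_activity": ""
            if v.measured_activity is None
            else repr(float(v.measured_activity)),
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=list(VARIANT_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )
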