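"""Sequence and label I/O, and the feature-schema registry.

This module owns the single source of truth for the 776-slot feature
schema: every feature emitted by :mod:`shortprot.features_core` and
:mod:`shortprot.features_motifs` is registered here, exactly once, in a
fixed order. Tabular feature I/O round-trips bit-for-bit because values
are written with 17 significant digits (lossless for IEEE doubles).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET_SET = frozenset(ALPHABET)

#: amino-acid classes used by the grouped (C/T/D) encoding
GROUP_CLASSES = "abcdef"
GROUP_OF = {}
for _cls, _members in (("a", "IVLM"), ("b", "FYW"), ("c", "HKR"),
                       ("d", "DE"), ("e", "QNTP"), ("f", "ACGS")):
    for _res in _members:
        GROUP_OF[_res] = _cls

PSI_CUTOFF_DEFAULT = 2.0  # PSI below this ~ half-life under 30 minutes


class Label(str, Enum):
    SHORT = "SHORT"
    LONG = "LONG"


class Category(str, Enum):
    AA_CONTENT = "AA_CONTENT"
    GROUPED = "GROUPED"
    PHYSCHEM = "PHYSCHEM"
    STRUCTURE = "STRUCTURE"
    DEGRADATION = "DEGRADATION"
    PTM = "PTM"


class ValidationError(ValueError):
    """Input failed a contract check (alphabet, table format, schema)."""


class EmptyInputError(ValidationError):
    pass


@dataclass
class ProteinRecord:
    """One protein: identifier, residues, optional stability annotation.

    ``psi`` is the Protein Stability Index; proteins with PSI < 2.0
    (roughly a 30-minute half-life) are the short-lived class.
    """

    id: str
    sequence: str
    psi: Optional[float] = None
    label: Optional[Label] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = [(i, c) for i, c in enumerate(self.sequence) if c not in ALPHABET_SET]
        if bad:
            i, c = bad[0]
            raise ValidationError(
                f"record {self.id!r}: invalid residue {c!r} at position {i + 1}"
            )
        if self.psi is not None and self.psi < 0:
            raise ValidationError(f"record {self.id!r}: negative PSI {self.psi}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered, named feature slots with category bookkeeping."""

    names: tuple
    categories: tuple  # Category per slot
    #: slots holding counts/lengths of sequence regions; these are stored
    #: already divided by sequence length in the feature vector
    length_normalized: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if len(self.names) != len(set(self.names)):
            raise ValidationError("duplicate feature names in schema")
        if len(self.names) != len(self.categories):
            raise ValidationError("names/categories length mismatch")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self._index_map[name]

    @property
    def _index_map(self):
        # cached lazily on the instance despite frozen dataclass
        m = object.__getattribute__(self, "__dict__").get("_imap")
        if m is None:
            m = {n: i for i, n in enumerate(self.names)}
            object.__getattribute__(self, "__dict__")["_imap"] = m
        return m

    def category_counts(self) -> dict:
        out: dict = {}
        for c in self.categories:
            out[c] = out.get(c, 0) + 1
        return out


@dataclass
class FeatureVector:
    schema: FeatureSchema
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.schema),):
            raise ValidationError(
                f"feature vector length {self.values.shape} != schema length {len(self.schema)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite feature value")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.schema.index(name)])


def _dbox_names():
    return ["D_g", "D_cA", "D_cB", "D_s"]


def build_schema() -> FeatureSchema:
    """Construct the canonical 776-slot schema.

    Blocks, in order: mono-peptide (20) + di-peptide (400) composition;
    grouped-class single (6) + dyad (36) + triplet (216) composition,
    transition (15), distribution (30); physicochemical (4); structure
    (7 = disorder 4 + secondary structure 3); degradation motifs (35 =
    KEN 1 + D-box 4 + PEST 4 + LCR 3 + N-terminal 20 + SP 1 + TM 2);
    post-translational modification (7).
    """
    names: list = []
    cats: list = []

    def add(block: Iterable[str], cat: Category):
        for n in block:
            names.append(n)
            cats.append(cat)

    add((f"AA_{a}" for a in ALPHABET), Category.AA_CONTENT)
    add((f"AA_{a}{b}" for a, b in itertools.product(ALPHABET, repeat=2)),
        Category.AA_CONTENT)

    add((f"aa_{g}" for g in GROUP_CLASSES), Category.GROUPED)
    add((f"aa_{a}{b}" for a, b in itertools.product(GROUP_CLASSES, repeat=2)),
        Category.GROUPED)
    add(("aa_" + "".join(t) for t in itertools.product(GROUP_CLASSES, repeat=3)),
        Category.GROUPED)
    add((f"{a}_>{b}" for a, b in itertools.combinations(GROUP_CLASSES, 2)),
        Category.GROUPED)
    add((f"num%{g}_{q}" for g in GROUP_CLASSES
         for q in ("1st", "25%", "50%", "75%", "100%")), Category.GROUPED)

    add(["len.", "isoele.", "Sulphur", "Hydrophobicity"], Category.PHYSCHEM)

    add(["disorder_len", "disorder_score", "disorder_num", "disorder_max",
         "helix", "sheet", "turn"], Category.STRUCTURE)

    add(["KEN"] + _dbox_names()
        + ["PEST_num", "PEST_max", "PEST_score", "PEST_posi",
           "LCR_len.", "LCR_num", "LCR_max"]
        + [f"N_{a}" for a in ALPHABET]
        + ["SP", "TM", "TM_len."], Category.DEGRADATION)

    add(["Phos_S", "Phos_T", "Phos_Y", "Cglyc", "Nglyc", "Oglyc_S", "Oglyc_T"],
        Category.PTM)

    length_normalized = frozenset(
        _dbox_names()
        + ["PEST_num", "PEST_max", "LCR_len.", "LCR_num", "LCR_max",
           "disorder_len", "disorder_num", "disorder_max", "TM_len.",
           "Phos_S", "Phos_T", "Phos_Y", "Cglyc", "Nglyc", "Oglyc_S", "Oglyc_T"]
    )
    return FeatureSchema(tuple(names), tuple(cats), length_normalized)


#: module-level singleton schema registry
SCHEMA = build_schema()

#: the reduced optimal feature set, in fixed report order
REDUCED11 = ("TM", "Hydrophobicity", "SP", "aa_ba", "aa_aab", "len.",
             "aa_da", "AA_D", "aa_cd", "AA_LL", "aa_bb")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, strict: bool = False) -> list:
    """Read protein records from FASTA.

    Residues are uppercased. Records containing residues outside the
    standard 20-letter alphabet (B, J, O, U, X, Z, ``*`` ...) are
    rejected with :class:`ValidationError` in strict mode, or skipped
    with a logged count in lenient mode (the default).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"FASTA file not found: {path}")
    records = []
    skipped = 0
    n_entries = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        n_entries += 1
        seq = str(entry.seq).upper()
        bad = next(((i, c) for i, c in enumerate(seq) if c not in ALPHABET_SET), None)
        if bad is not None or len(seq) == 0:
            if strict:
                if bad is None:
                    raise ValidationError(f"record {entry.id!r}: empty sequence")
                i, c = bad
                raise ValidationError(
                    f"record {entry.id!r}: invalid residue {c!r} at position {i + 1}"
                )
            skipped += 1
            continue
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if n_entries == 0:
        raise EmptyInputError(f"no FASTA entries in {path}")
    if skipped:
        logger.info("read_fasta: skipped %d record(s) with non-standard residues", skipped)
    return records


def write_fasta(records: Sequence[ProteinRecord], path, width: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# PSI label table

def read_psi_table(path, cutoff: float = PSI_CUTOFF_DEFAULT) -> dict:
    """Read a two-column (id, PSI) table; label SHORT iff PSI < cutoff."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"PSI table not found: {path}")
    out: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValidationError(f"line {lineno}: expected 2 columns, got {len(parts)}")
            pid, raw = parts[0], parts[1]
            if pid == "id" and lineno == 1:
                continue  # optional header
            try:
                psi = float(raw)
            except ValueError:
                raise ValidationError(f"line {lineno}: non-numeric PSI {raw!r}") from None
            if pid in out:
                raise ValidationError(f"line {lineno}: duplicate id {pid!r}")
            out[pid] = (psi, Label.SHORT if psi < cutoff else Label.LONG)
    return out


def write_psi_table(records: Sequence[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tPSI\n")
        for rec in records:
            if rec.psi is None:
                raise ValidationError(f"record {rec.id!r} has no PSI")
            fh.write(f"{rec.id}\t{rec.psi:.6g}\n")


# ---------------------------------------------------------------------------
# Feature tables (TSV; header = feature names; first column = id)

FLOAT_FMT = "%.17g"  # lossless for float64, hence bit-exact round-trips


def write_feature_table(ids: Sequence[str], vectors: Sequence[FeatureVector], path) -> None:
    if len(ids) != len(vectors):
        raise ValidationError("ids/vectors length mismatch")
    if not vectors:
        raise EmptyInputError("no feature vectors to write")
    schema = vectors[0].schema
    for v in vectors[1:]:
        if v.schema.names != schema.names:
            raise ValidationError("feature vectors do not share one schema")
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(schema.names) + "\n")
        for pid, vec in zip(ids, vectors):
            row = "\t".join(FLOAT_FMT % x for x in vec.values)
            fh.write(f"{pid}\t{row}\n")


def read_feature_table(path, schema: Optional[FeatureSchema] = None):
    """Read a feature table; returns ``(names, matrix, ids)``.

    If ``schema`` is given, the header must match its names exactly.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"feature table not found: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "id":
            raise ValidationError("feature table must start with an 'id' column")
        names = tuple(header[1:])
        if schema is not None and names != schema.names:
            raise ValidationError(
                f"schema mismatch: table has {len(names)} features, "
                f"expected {len(schema.names)}"
            )
        ids = []
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(names) + 1:
                raise ValidationError(
                    f"line {lineno}: {len(parts) - 1} values, expected {len(names)}"
                )
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return names, np.asarray(rows, dtype=float), ids


# ---------------------------------------------------------------------------
# Redundancy-filter hook (requires BLAST + a real dataset; intentionally
# left unimplemented)

def cluster_by_identity(records: Sequence[ProteinRecord], identity: float = 0.2):
    """Hook for sequence-identity redundancy filtering (e.g. 20% cutoff).

    Not implemented: requires an all-vs-all aligner (BLAST) and is only
    meaningful on real proteome datasets. Run BLAST externally and
    filter the FASTA before feeding it to this package.
    """
    raise NotImplementedError(
        "redundancy filtering is not packaged; cluster externally with BLAST "
        "(e.g. blastp all-vs-all, drop members of clusters above "
        f"{identity:.0%} identity) and pass the filtered FASTA"
    )
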