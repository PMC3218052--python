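"""Amino-acid content, grouped-class C/T/D encoding, physicochemical features.

Covers the 723 composition slots (20 mono + 400 di-peptide; 258 grouped
composition + 15 transition + 30 distribution) and the 4 physicochemical
slots (length, isoelectric point, sulphur content, mean hydropathy), plus
the reduced 11-feature extractor.

Conventions for short sequences: a k-mer block whose window does not fit
(L < k) is all zeros. Distribution values for an absent class are all
zeros.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, Sequence

import numpy as np

from .seqio import (ALPHABET, GROUP_CLASSES, GROUP_OF, REDUCED11, SCHEMA,
                    ProteinRecord, ValidationError)

AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}
GROUP_INDEX = {g: i for i, g in enumerate(GROUP_CLASSES)}

#: Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE: Dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: EMBOSS pKa values for the charge model behind the isoelectric point
EMBOSS_PKA: Dict[str, float] = {
    "Nterm": 8.6, "Cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
    "K": 10.8, "R": 12.5, "Y": 10.1,
}

_POSITIVE = ("Nterm", "H", "K", "R")
_NEGATIVE = ("Cterm", "C", "D", "E", "Y")


def _require_nonempty(sequence: str) -> None:
    if len(sequence) < 1:
        raise ValidationError("empty sequence")


def aa_composition(sequence: str) -> np.ndarray:
    """Relative frequency of each of the 20 residues (alphabetical order)."""
    _require_nonempty(sequence)
    counts = np.zeros(20)
    for c in sequence:
        counts[AA_INDEX[c]] += 1
    return counts / len(sequence)


def dipeptide_composition(sequence: str) -> np.ndarray:
    """Overlapping ordered-pair frequencies, count/(L-1); 400 slots.

    A length-1 sequence yields all zeros.
    """
    _require_nonempty(sequence)
    out = np.zeros(400)
    L = len(sequence)
    if L < 2:
        return out
    for i in range(L - 1):
        out[AA_INDEX[sequence[i]] * 20 + AA_INDEX[sequence[i + 1]]] += 1
    return out / (L - 1)


def group_sequence(sequence: str) -> str:
    """Map residues onto the six physicochemical classes a-f."""
    _require_nonempty(sequence)
    return "".join(GROUP_OF[c] for c in sequence)


def grouped_composition(grouped: str) -> np.ndarray:
    """Single (6) + dyad (36) + triplet (216) class composition = 258 slots.

    Dyads and triplets are overlapping windows normalized by L-1 and L-2;
    a block is all-zero when the sequence is shorter than its window.
    """
    _require_nonempty(grouped)
    L = len(grouped)
    idx = np.array([GROUP_INDEX[c] for c in grouped])
    single = np.bincount(idx, minlength=6).astype(float) / L
    dyad = np.zeros(36)
    if L >= 2:
        codes = idx[:-1] * 6 + idx[1:]
        dyad = np.bincount(codes, minlength=36).astype(float) / (L - 1)
    triplet = np.zeros(216)
    if L >= 3:
        codes = idx[:-2] * 36 + idx[1:-1] * 6 + idx[2:]
        triplet = np.bincount(codes, minlength=216).astype(float) / (L - 2)
    return np.concatenate([single, dyad, triplet])


#: fixed order of the 15 unordered class pairs
TRANSITION_PAIRS = tuple(itertools.combinations(GROUP_CLASSES, 2))


def grouped_transition(grouped: str) -> np.ndarray:
    """Unordered class-pair transition frequencies: (n_xy + n_yx)/(L-1)."""
    _require_nonempty(grouped)
    L = len(grouped)
    out = np.zeros(15)
    if L < 2:
        return out
    pair_index = {p: i for i, p in enumerate(TRANSITION_PAIRS)}
    for x, y in zip(grouped[:-1], grouped[1:]):
        if x == y:
            continue
        key = (x, y) if x < y else (y, x)
        out[pair_index[key]] += 1
    return out / (L - 1)


def grouped_distribution(grouped: str) -> np.ndarray:
    """Per class: positions of the 1st/25%/50%/75%/100% occurrence, as %L.

    The k% occurrence is the ceil(k * n_class)-th occurrence (at least the
    first); values are 1-based positions divided by L, times 100. A class
    with no occurrences contributes five zeros.
    """
    _require_nonempty(grouped)
    L = len(grouped)
    out = np.zeros(30)
    for gi, g in enumerate(GROUP_CLASSES):
        positions = [i + 1 for i, c in enumerate(grouped) if c == g]
        n = len(positions)
        if n == 0:
            continue
        for qi, frac in enumerate((None, 0.25, 0.50, 0.75, 1.00)):
            k = 1 if frac is None else max(1, math.ceil(frac * n))
            out[gi * 5 + qi] = positions[k - 1] / L * 100.0
    return out


def net_charge(sequence: str, ph: float) -> float:
    """Net charge of the sequence at a given pH under the EMBOSS pKa model."""
    counts = {aa: sequence.count(aa) for aa in "CDEHKRY"}
    counts["Nterm"] = 1
    counts["Cterm"] = 1
    charge = 0.0
    for grp in _POSITIVE:
        charge += counts.get(grp, 0) / (1.0 + 10.0 ** (ph - EMBOSS_PKA[grp]))
    for grp in _NEGATIVE:
        charge -= counts.get(grp, 0) / (1.0 + 10.0 ** (EMBOSS_PKA[grp] - ph))
    return charge


def isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14]."""
    _require_nonempty(sequence)
    lo, hi = 0.0, 14.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        q = net_charge(sequence, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gravy(sequence: str) -> float:
    """Grand average of hydropathy (mean Kyte-Doolittle value)."""
    _require_nonempty(sequence)
    return sum(KYTE_DOOLITTLE[c] for c in sequence) / len(sequence)


def physicochemical(sequence: str) -> np.ndarray:
    """[length, isoelectric point, sulphur content, GRAVY]."""
    _require_nonempty(sequence)
    L = len(sequence)
    sulphur = (sequence.count("C") + sequence.count("M")) / L
    return np.array([float(L), isoelectric_point(sequence), sulphur, gravy(sequence)])


def core_feature_block(sequence: str) -> np.ndarray:
    """The 727 core slots: AA content (420) + grouped CTD (303) + physchem (4)."""
    grouped = group_sequence(sequence)
    return np.concatenate([
        aa_composition(sequence),
        dipeptide_composition(sequence),
        grouped_composition(grouped),
        grouped_transition(grouped),
        grouped_distribution(grouped),
        physicochemical(sequence),
    ])


def extract_reduced11(record: ProteinRecord, backends=None) -> np.ndarray:
    """The reduced optimal 11-feature vector, as a projection of the full one.

    Order: TM, Hydrophobicity, SP, aa_ba, aa_aab, len., aa_da, AA_D,
    aa_cd, AA_LL, aa_bb. Values are taken from the full 776-slot vector
    so there is no recomputation drift.
    """
    from .features_motifs import extract_features
    full = extract_features(record, backends=backends)
    return np.array([full[name] for name in REDUCED11])
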