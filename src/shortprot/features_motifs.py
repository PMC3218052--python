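"""Degradation-motif, structural and PTM features, and full-vector assembly.

Implements the 35 degradation-motif slots (KEN box, destruction-box
families, PEST regions, SEG low-complexity regions, N-terminal residue
one-hot, signal peptide, transmembrane), the 7 structure slots (disorder,
secondary structure) and the 7 PTM slots (phospho-S/T/Y, C-/N-/O-
glycosylation sequons).

External predictors (PSIPRED, SignalP, TMHMM, IUPred, per-site PTM
predictors, the destruction-box block tool) are pluggable: each feature
has a deterministic in-process default heuristic, and a file-reader
backend that injects real tool output while honouring the same output
contract. The default D-box scorer matches the RxxL destruction-box core
with documented family-specific context rules; it is a stand-in for the
original block-based tool, whose blocks are not published.

All region coordinates are 0-based, half-open.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .features_core import KYTE_DOOLITTLE, core_feature_block
from .seqio import ALPHABET, SCHEMA, FeatureVector, ProteinRecord, ValidationError

AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}


@dataclass(frozen=True)
class Region:
    """A located subsequence hit; start/end are 0-based half-open."""

    kind: str  # PEST | LCR | TM | DISORDER
    start: int
    end: int
    score: float = 0.0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(f"bad region bounds [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def render(self) -> str:
        """Human-readable 1-based inclusive coordinates."""
        return f"{self.kind} {self.start + 1}-{self.end} score={self.score:.3f}"


def _merge_regions(regions: List[Region]) -> List[Region]:
    """Merge overlapping/adjacent same-kind regions; max score wins."""
    if not regions:
        return []
    regions = sorted(regions, key=lambda r: (r.start, r.end))
    merged = [regions[0]]
    for r in regions[1:]:
        last = merged[-1]
        if r.start <= last.end:
            merged[-1] = Region(last.kind, last.start, max(last.end, r.end),
                                max(last.score, r.score))
        else:
            merged.append(r)
    return merged


# ---------------------------------------------------------------------------
# KEN box and destruction box

_KEN_RE = re.compile(r"(?=(KEN...[ND]))")


def find_ken_box(sequence: str) -> Tuple[int, List[Region]]:
    """KENxxxN/D motif scan; overlapping occurrences all reported."""
    hits = [Region("KEN", m.start(), m.start() + 7)
            for m in _KEN_RE.finditer(sequence)]
    return (1 if hits else 0), hits


# Family-specific context rules around the RxxL destruction-box core.
# These are documented stand-ins for the original family blocks:
#   geminin : RxxL with an acidic residue (D/E) at core offset +6
#   cyclin A: RxxL with N at core offset +8
#   cyclin B: RxxL immediately followed by G (RxxLG)
#   securin : the bare RxxL core
_DBOX_RES = [
    ("D_g", re.compile(r"(?=(R..L..[DE]))")),
    ("D_cA", re.compile(r"(?=(R..L....N))")),
    ("D_cB", re.compile(r"(?=(R..LG))")),
    ("D_s", re.compile(r"(?=(R..L))")),
]


def find_dbox(sequence: str, backend: Optional["DboxReader"] = None,
              record_id: Optional[str] = None) -> np.ndarray:
    """Destruction-box family content: geminin, cyclin A, cyclin B, securin.

    Default backend counts RxxL-core matches under the family context
    rules above (raw counts; divided by length at vector assembly). A
    reader backend injects scores from external tool output.
    """
    if backend is not None:
        return backend.get(record_id)
    return np.array([float(len(rx.findall(sequence))) for _, rx in _DBOX_RES])


# ---------------------------------------------------------------------------
# PEST regions (epestfind-style)

#: average residue masses (Da) for the mass-fraction term of the PEST score
RESIDUE_MASS: Dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

PEST_MIN_LEN = 12
PEST_THRESHOLD = 5.0
_BASIC = frozenset("RKH")


def pest_score(segment: str) -> float:
    """Hydrophobicity-corrected D/E/P/S/T mass-fraction PEST score.

    score = 0.55 * DEPST - 0.5 * HI, where DEPST is the mass percent of
    D/E/P/S/T residues in the segment corrected by one equivalent each of
    (D|E), P and (S|T) (preferring D over E and S over T when both are
    present), and HI is the mole-percent-weighted Kyte-Doolittle
    hydropathy rescaled to 0..90 (10*KD + 45). Potential PEST regions
    score above +5.
    """
    total_mass = sum(RESIDUE_MASS[c] for c in segment)
    depst_mass = sum(RESIDUE_MASS[c] for c in segment if c in "DEPST")
    depst_mass -= RESIDUE_MASS["D" if "D" in segment else "E"]
    depst_mass -= RESIDUE_MASS["P"]
    depst_mass -= RESIDUE_MASS["S" if "S" in segment else "T"]
    depst = 100.0 * depst_mass / total_mass
    hi = sum((10.0 * KYTE_DOOLITTLE[c] + 45.0) for c in segment) / len(segment)
    return 0.55 * depst - 0.5 * hi


def find_pest(sequence: str) -> Tuple[List[Region], np.ndarray]:
    """Potential PEST regions and the 4 summary features.

    Candidate segments are the maximal stretches between positively
    charged flanks (R/K/H; sequence termini also act as boundaries) of
    length >= 12 that contain >= 1 P, >= 1 D/E and >= 1 S/T; candidates
    scoring above +5 are potential PEST regions. Features: number of
    regions, length of the longest, score of the top-scoring region, and
    relative midpoint position of the top-scoring region (midpoint/L).
    Counts and lengths are raw here; length normalization happens at
    vector assembly.
    """
    L = len(sequence)
    boundaries = [-1] + [i for i, c in enumerate(sequence) if c in _BASIC] + [L]
    regions: List[Region] = []
    for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
        start, end = b0 + 1, b1
        seg = sequence[start:end]
        if len(seg) < PEST_MIN_LEN:
            continue
        if "P" not in seg or not set(seg) & set("DE") or not set(seg) & set("ST"):
            continue
        s = pest_score(seg)
        if s >= PEST_THRESHOLD:
            regions.append(Region("PEST", start, end, s))
    if not regions:
        return [], np.zeros(4)
    best = max(regions, key=lambda r: r.score)
    feats = np.array([
        float(len(regions)),
        float(max(len(r) for r in regions)),
        best.score,
        (best.start + best.end) / 2.0 / L,
    ])
    return regions, feats


# ---------------------------------------------------------------------------
# Low-complexity regions (SEG-style entropy segmentation)

def window_entropy(window: str) -> float:
    """Shannon entropy (bits) of the residue counts in a window."""
    counts: Dict[str, int] = {}
    for c in window:
        counts[c] = counts.get(c, 0) + 1
    n = len(window)
    return -sum((k / n) * math.log2(k / n) for k in counts.values())


def find_lcr(sequence: str, window: int = 12, k1: float = 2.2,
             k2: float = 2.5) -> Tuple[List[Region], np.ndarray]:
    """SEG-style low-complexity segmentation.

    Windows with entropy <= k1 seed regions; each seed is extended over
    the maximal contiguous run of windows with entropy <= k2; overlapping
    regions are merged. Features: total length, count, max length (raw).
    """
    L = len(sequence)
    if L < window:
        return [], np.zeros(3)
    ent = [window_entropy(sequence[i:i + window]) for i in range(L - window + 1)]
    regions: List[Region] = []
    i = 0
    n_win = len(ent)
    while i < n_win:
        if ent[i] > k1:
            i += 1
            continue
        # extend left/right over the k2 run containing this seed
        lo = i
        while lo > 0 and ent[lo - 1] <= k2:
            lo -= 1
        hi = i
        while hi + 1 < n_win and ent[hi + 1] <= k2:
            hi += 1
        regions.append(Region("LCR", lo, hi + window,
                              score=min(ent[lo:hi + 1])))
        i = hi + 1
    regions = _merge_regions(regions)
    if not regions:
        return [], np.zeros(3)
    lengths = [len(r) for r in regions]
    return regions, np.array([float(sum(lengths)), float(len(regions)),
                              float(max(lengths))])


# ---------------------------------------------------------------------------
# N-terminal residue

def nterm_onehot(sequence: str) -> np.ndarray:
    """Indicator of which residue occupies position 1."""
    if not sequence:
        raise ValidationError("empty sequence")
    out = np.zeros(20)
    out[AA_INDEX[sequence[0]]] = 1.0
    return out


# ---------------------------------------------------------------------------
# Signal peptide and transmembrane heuristics

SP_H_WINDOW = 8
SP_KD_MIN = 1.6
SP_N_MAX = 12
TM_WINDOW = 19
TM_KD_MIN = 1.6


def predict_signal_peptide(sequence: str, backend: Optional["SignalPReader"] = None,
                           record_id: Optional[str] = None) -> int:
    """Existence of an N-terminal signal peptide (0/1).

    Default heuristic: within the first 40 residues there must be an
    h-region (an 8-residue window with mean Kyte-Doolittle >= 1.6)
    starting after an n-region of 1..12 residues that contains at least
    one K/R and no D/E.
    """
    if backend is not None:
        return backend.get(record_id)
    kd = [KYTE_DOOLITTLE[c] for c in sequence]
    L = len(sequence)
    for hs in range(1, min(SP_N_MAX, L - SP_H_WINDOW, 40 - SP_H_WINDOW) + 1):
        n_region = sequence[:hs]
        if not set(n_region) & set("KR"):
            continue
        if set(n_region) & set("DE"):
            continue
        if sum(kd[hs:hs + SP_H_WINDOW]) / SP_H_WINDOW >= SP_KD_MIN:
            return 1
    return 0


def predict_tm(sequence: str, backend: Optional["TmhmmReader"] = None,
               record_id: Optional[str] = None
               ) -> Tuple[int, int, List[Region]]:
    """Transmembrane segments: (exists 0/1, total length, regions).

    Default heuristic: every position covered by a 19-residue window with
    mean Kyte-Doolittle >= 1.6 is a TM candidate; maximal candidate runs
    of length >= 19 are TM regions.
    """
    if backend is not None:
        regions = backend.get(record_id)
    else:
        L = len(sequence)
        covered = np.zeros(L, dtype=bool)
        if L >= TM_WINDOW:
            kd = np.array([KYTE_DOOLITTLE[c] for c in sequence])
            csum = np.concatenate([[0.0], np.cumsum(kd)])
            for i in range(L - TM_WINDOW + 1):
                if (csum[i + TM_WINDOW] - csum[i]) / TM_WINDOW >= TM_KD_MIN:
                    covered[i:i + TM_WINDOW] = True
        regions = []
        i = 0
        while i < L:
            if not covered[i]:
                i += 1
                continue
            j = i
            while j < L and covered[j]:
                j += 1
            if j - i >= TM_WINDOW:
                regions.append(Region("TM", i, j))
            i = j
    total = sum(len(r) for r in regions)
    return (1 if regions else 0), total, regions


# ---------------------------------------------------------------------------
# Secondary structure (Chou-Fasman propensity default; PSIPRED reader)

#: Chou-Fasman conformational propensities (helix, sheet, turn)
CHOU_FASMAN: Dict[str, Tuple[float, float, float]] = {
    "A": (142, 83, 66), "R": (98, 93, 95), "N": (67, 89, 156),
    "D": (101, 54, 146), "C": (70, 119, 119), "Q": (111, 110, 98),
    "E": (151, 37, 74), "G": (57, 75, 156), "H": (100, 87, 95),
    "I": (108, 160, 47), "L": (121, 130, 59), "K": (114, 74, 101),
    "M": (145, 105, 60), "F": (113, 138, 60), "P": (57, 55, 152),
    "S": (77, 75, 143), "T": (83, 119, 96), "W": (108, 137, 96),
    "Y": (69, 147, 114), "V": (106, 170, 50),
}


def predict_secondary_structure(sequence: str,
                                backend: Optional["PsipredReader"] = None,
                                record_id: Optional[str] = None) -> np.ndarray:
    """Helix/sheet/coil content fractions (sum to 1).

    Default backend assigns each residue the state with the highest
    Chou-Fasman propensity; a reader backend parses PSIPRED .ss2/.horiz
    output.
    """
    if backend is not None:
        return backend.get(record_id)
    if not sequence:
        raise ValidationError("empty sequence")
    counts = [0, 0, 0]
    for c in sequence:
        p = CHOU_FASMAN[c]
        counts[int(np.argmax(p))] += 1
    return np.array(counts, dtype=float) / len(sequence)


# ---------------------------------------------------------------------------
# Disorder (TOP-IDP propensity default; IUPred reader)

#: TOP-IDP disorder propensity scale (higher = more disorder-promoting)
TOP_IDP: Dict[str, float] = {
    "A": 0.06, "R": 0.180, "N": 0.007, "D": 0.192, "C": 0.02,
    "Q": 0.318, "E": 0.736, "G": 0.166, "H": 0.303, "I": -0.486,
    "L": -0.326, "K": 0.586, "M": -0.397, "F": -0.697, "P": 0.987,
    "S": 0.341, "T": 0.059, "W": -0.884, "Y": -0.510, "V": -0.121,
}

DISORDER_SMOOTH = 21
DISORDER_MIN_LEN = 30
DISORDER_THRESHOLD = 0.0  # for the TOP-IDP default scale
IUPRED_THRESHOLD = 0.5    # for IUPred per-residue scores


def _regions_from_scores(scores: np.ndarray, threshold: float,
                         min_len: int) -> List[Region]:
    regions: List[Region] = []
    L = len(scores)
    i = 0
    while i < L:
        if scores[i] <= threshold:
            i += 1
            continue
        j = i
        while j < L and scores[j] > threshold:
            j += 1
        if j - i >= min_len:
            regions.append(Region("DISORDER", i, j,
                                  score=float(np.mean(scores[i:j]))))
        i = j
    return regions


def predict_disorder(sequence: str, backend: Optional["IupredReader"] = None,
                     record_id: Optional[str] = None
                     ) -> Tuple[np.ndarray, List[Region]]:
    """Disorder features: (number, total length, max length, mean score).

    Default backend: per-residue TOP-IDP propensity smoothed over a
    21-residue window; positions above 0 form candidates; regions of
    >= 30 residues are reported. A reader backend consumes IUPred
    per-residue scores (threshold 0.5). Counts/lengths are raw here.
    """
    if backend is not None:
        scores = backend.get(record_id)
        threshold = IUPRED_THRESHOLD
    else:
        raw = np.array([TOP_IDP[c] for c in sequence])
        half = DISORDER_SMOOTH // 2
        L = len(raw)
        csum = np.concatenate([[0.0], np.cumsum(raw)])
        scores = np.empty(L)
        for i in range(L):
            lo, hi = max(0, i - half), min(L, i + half + 1)
            scores[i] = (csum[hi] - csum[lo]) / (hi - lo)
        threshold = DISORDER_THRESHOLD
    regions = _regions_from_scores(np.asarray(scores, dtype=float), threshold,
                                   DISORDER_MIN_LEN)
    if not regions:
        return np.zeros(4), []
    lengths = [len(r) for r in regions]
    feats = np.array([
        float(len(regions)), float(sum(lengths)), float(max(lengths)),
        float(np.mean([r.score for r in regions])),
    ])
    return feats, regions


# ---------------------------------------------------------------------------
# PTM sites (sequon / kinase-context defaults; per-site table reader)

_PTM_KINDS = ("Phos_S", "Phos_T", "Phos_Y", "Cglyc", "Nglyc", "Oglyc_S", "Oglyc_T")


def count_ptm_sites(sequence: str, backend: Optional["PtmTableReader"] = None,
                    record_id: Optional[str] = None) -> np.ndarray:
    """Counts of predicted modification sites (7 values, raw counts).

    Default sequon/context backend:
      phospho-S/T: S or T followed by P, or preceded by R at -3 (RxxS/T);
      phospho-Y:   Y with >= 2 acidic residues (D/E) within +-5;
      C-glyc:      W-x-x-W;
      N-glyc:      N-{P}-[S/T];
      O-glyc S/T:  S or T with >= 2 prolines within +-5.
    Counts are divided by sequence length at vector assembly ("content").
    """
    if backend is not None:
        return backend.get(record_id)
    L = len(sequence)
    out = np.zeros(7)
    for i, c in enumerate(sequence):
        nxt = sequence[i + 1] if i + 1 < L else ""
        win = sequence[max(0, i - 5):i] + sequence[i + 1:i + 6]
        if c in "ST":
            kinase = nxt == "P" or (i >= 3 and sequence[i - 3] == "R")
            if kinase:
                out[0 if c == "S" else 1] += 1
            if win.count("P") >= 2:
                out[5 if c == "S" else 6] += 1
        elif c == "Y":
            if win.count("D") + win.count("E") >= 2:
                out[2] += 1
        if c == "W" and i + 3 < L and sequence[i + 3] == "W":
            out[3] += 1
        if c == "N" and i + 2 < L and nxt != "P" and sequence[i + 2] in "ST":
            out[4] += 1
    return out


# ---------------------------------------------------------------------------
# Reader backends for real external-tool output

class _ReaderBase:
    name = "reader"

    def __init__(self):
        self._data: Dict[str, object] = {}

    def get(self, record_id: Optional[str]):
        if record_id is None or record_id not in self._data:
            raise ValidationError(
                f"{self.name} backend has no record for id {record_id!r}")
        return self._data[record_id]


class PsipredReader(_ReaderBase):
    """Reads PSIPRED per-protein .ss2 or .horiz files into SS fractions."""

    name = "psipred"

    def add_ss2(self, record_id: str, path) -> None:
        counts = {"H": 0, "E": 0, "C": 0}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 3:
                    raise ValidationError(f"{path}: line {lineno}: malformed .ss2 row")
                state = parts[2]
                if state not in counts:
                    raise ValidationError(
                        f"{path}: line {lineno}: unknown state {state!r}")
                counts[state] += 1
        total = sum(counts.values())
        if total == 0:
            raise ValidationError(f"{path}: no residue rows")
        self._data[record_id] = np.array(
            [counts["H"], counts["E"], counts["C"]], dtype=float) / total

    def add_horiz(self, record_id: str, path) -> None:
        states: List[str] = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("Pred:"):
                    states.extend(line.split(":", 1)[1].strip())
        if not states:
            raise ValidationError(f"{path}: no Pred: lines")
        arr = np.array([states.count("H"), states.count("E"),
                        states.count("C")], dtype=float)
        self._data[record_id] = arr / len(states)


class IupredReader(_ReaderBase):
    """Reads IUPred per-residue output: '<pos> [<aa>] <score>' lines."""

    name = "iupred"

    def add(self, record_id: str, path) -> None:
        scores: List[float] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ValidationError(f"{path}: line {lineno}: malformed row")
                try:
                    scores.append(float(parts[-1]))
                except ValueError:
                    raise ValidationError(
                        f"{path}: line {lineno}: non-numeric score") from None
        if not scores:
            raise ValidationError(f"{path}: no score rows")
        self._data[record_id] = np.array(scores)


class SignalPReader(_ReaderBase):
    """Reads SignalP short-format tables: '<id> ... <Y|N>' data lines."""

    name = "signalp"

    def __init__(self, path=None):
        super().__init__()
        if path is not None:
            self.add_table(path)

    def add_table(self, path) -> None:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2 or parts[-1] not in ("Y", "N"):
                    raise ValidationError(
                        f"{path}: line {lineno}: expected trailing Y/N flag")
                self._data[parts[0]] = 1 if parts[-1] == "Y" else 0


class TmhmmReader(_ReaderBase):
    """Reads TMHMM-style region lines: '<id> TMhelix <start> <end>' (1-based)."""

    name = "tmhmm"

    def __init__(self, path=None):
        super().__init__()
        self._seen: set = set()
        if path is not None:
            self.add_table(path)

    def add_table(self, path) -> None:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ValidationError(f"{path}: line {lineno}: malformed row")
                pid = parts[0]
                self._seen.add(pid)
                self._data.setdefault(pid, [])
                if parts[1] == "none":
                    continue
                if parts[1] != "TMhelix" or len(parts) < 4:
                    raise ValidationError(
                        f"{path}: line {lineno}: expected 'TMhelix start end'")
                start, end = int(parts[2]) - 1, int(parts[3])
                self._data[pid].append(Region("TM", start, end))
        for pid in self._seen:
            self._data[pid] = _merge_regions(self._data[pid])


class PtmTableReader(_ReaderBase):
    """Reads generic per-site PTM tables: '<id> <pos> <kind>' lines."""

    name = "ptm"

    def __init__(self, path=None):
        super().__init__()
        if path is not None:
            self.add_table(path)

    def add_table(self, path) -> None:
        kind_index = {k: i for i, k in enumerate(_PTM_KINDS)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 3 or parts[2] not in kind_index:
                    raise ValidationError(
                        f"{path}: line {lineno}: expected '<id> <pos> <kind>' "
                        f"with kind in {_PTM_KINDS}")
                pid = parts[0]
                if pid not in self._data:
                    self._data[pid] = np.zeros(7)
                self._data[pid][kind_index[parts[2]]] += 1


class DboxReader(_ReaderBase):
    """Reads external D-box tool output: '<id> <D_g> <D_cA> <D_cB> <D_s>'."""

    name = "dbox"

    def __init__(self, path=None):
        super().__init__()
        if path is not None:
            self.add_table(path)

    def add_table(self, path) -> None:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 5:
                    raise ValidationError(
                        f"{path}: line {lineno}: expected id + 4 family scores")
                self._data[parts[0]] = np.array([float(x) for x in parts[1:]])


@dataclass
class Backends:
    """Pluggable predictor backends; None means the in-process default."""

    sp: Optional[SignalPReader] = None
    tm: Optional[TmhmmReader] = None
    ss: Optional[PsipredReader] = None
    disorder: Optional[IupredReader] = None
    ptm: Optional[PtmTableReader] = None
    dbox: Optional[DboxReader] = None

    @property
    def capabilities(self) -> set:
        caps = set()
        for cap, reader in (("SP", self.sp), ("TM", self.tm), ("SS", self.ss),
                            ("DISORDER", self.disorder), ("PTM", self.ptm)):
            if reader is not None:
                caps.add(cap)
        return caps


DEFAULT_BACKENDS = Backends()


# ---------------------------------------------------------------------------
# Full 776-slot assembly

def extract_features(record: ProteinRecord,
                     backends: Optional[Backends] = None) -> FeatureVector:
    """Assemble the full 776-slot feature vector for one record.

    Region-derived counts and lengths (slots flagged in the schema) are
    divided by sequence length; fractions and scores are left as-is.
    Deterministic for fixed backends and sequence.
    """
    if backends is None:
        backends = DEFAULT_BACKENDS
    seq = record.sequence
    L = len(seq)

    def _block(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ValidationError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise ValidationError(
                f"feature block {name!r} failed for record {record.id!r}: {exc}"
            ) from exc

    core = _block("core", core_feature_block, seq)

    dis_feats, _ = _block("disorder", predict_disorder, seq,
                          backend=backends.disorder, record_id=record.id)
    n_dis, len_dis, max_dis, score_dis = dis_feats
    ss = _block("secondary_structure", predict_secondary_structure, seq,
                backend=backends.ss, record_id=record.id)
    structure = np.array([len_dis, score_dis, n_dis, max_dis,
                          ss[0], ss[1], ss[2]])

    ken, _ = _block("ken_box", find_ken_box, seq)
    dbox = _block("dbox", find_dbox, seq, backend=backends.dbox,
                  record_id=record.id)
    _, pest = _block("pest", find_pest, seq)
    _, lcr = _block("lcr", find_lcr, seq)
    nterm = _block("nterm", nterm_onehot, seq)
    sp = _block("signal_peptide", predict_signal_peptide, seq,
                backend=backends.sp, record_id=record.id)
    tm_exists, tm_len, _ = _block("tm", predict_tm, seq, backend=backends.tm,
                                  record_id=record.id)
    degradation = np.concatenate([
        [float(ken)], dbox, pest, lcr, nterm,
        [float(sp), float(tm_exists), float(tm_len)],
    ])

    ptm = _block("ptm", count_ptm_sites, seq, backend=backends.ptm,
                 record_id=record.id)

    values = np.concatenate([core, structure, degradation, ptm])
    norm_idx = [SCHEMA.index(n) for n in SCHEMA.length_normalized]
    values[norm_idx] = values[norm_idx] / L
    return FeatureVector(SCHEMA, values)


def extract_matrix(records: Sequence[ProteinRecord],
                   backends: Optional[Backends] = None) -> np.ndarray:
    """Feature matrix (n_records x 776) in schema order."""
    return np.vstack([extract_features(r, backends).values for r in records])
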