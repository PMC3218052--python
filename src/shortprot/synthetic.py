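"""Synthetic labeled proteomes with planted degradation-associated signals.

Emulates a proteome of short-lived vs long-lived proteins carrying the
class-conditional signals the classifier is built to exploit: signal-
peptide-like N-termini (45% of short-lived vs 3% of long-lived),
transmembrane hydrophobic segments, elevated hydrophobic/aromatic content
in short-lived proteins and elevated D/E content in long-lived proteins.
Default class sizes are 510 short-lived among 4838 proteins.

Residues are drawn i.i.d. from class-conditional compositions (a
vertebrate-like background with log-odds shifts); cassettes overwrite
residues in place so sequence lengths are unchanged. Generation is
deterministic per seed. An optional PSI value per record (log-normal,
median 1.2 for SHORT / 4.5 for LONG, truncated at the 2.0 cutoff) is
drawn only so label-table round-trips can be exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .seqio import ALPHABET, Label, ProteinRecord, ValidationError, write_fasta, write_psi_table

#: vertebrate-like background amino-acid frequencies
BACKGROUND_FREQS: Dict[str, float] = {
    "A": 0.070, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.037,
    "G": 0.066, "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100,
    "M": 0.021, "N": 0.036, "P": 0.063, "Q": 0.048, "R": 0.056,
    "S": 0.083, "T": 0.053, "V": 0.060, "W": 0.011, "Y": 0.029,
}

HYDROPHOBIC = "IVLMFYW"
ACIDIC = "DE"


@dataclass
class GeneratorConfig:
    n_short: int = 510
    n_long: int = 4328
    seed: int = 0
    p_sp_short: float = 0.45
    p_sp_long: float = 0.03
    p_tm_short: float = 0.35
    p_tm_long: float = 0.10
    #: extra log-odds of I/V/L/M/F/Y/W in the short-lived background
    hydrophobic_shift: float = 0.5
    #: extra log-odds of D/E in the long-lived background
    acidic_shift: float = 0.5
    #: log-normal length parameters (median, sigma of log) per class
    length_median_short: float = 450.0
    length_median_long: float = 350.0
    length_sigma: float = 0.45
    min_length: int = 60

    def __post_init__(self):
        for p in (self.p_sp_short, self.p_sp_long, self.p_tm_short, self.p_tm_long):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")
        if self.n_short < 1 or self.n_long < 1:
            raise ValidationError("class sizes must be >= 1")
        if self.min_length < 40:
            raise ValidationError(
                "min_length must be >= 40 so planted cassettes fit")


@dataclass(frozen=True)
class PlantedCassette:
    record_id: str
    kind: str  # SP | TM
    start: int
    end: int  # 0-based half-open


def class_composition(config: GeneratorConfig, label: Label) -> np.ndarray:
    """Class-conditional residue distribution (log-odds-shifted background)."""
    logits = np.log([BACKGROUND_FREQS[a] for a in ALPHABET])
    for i, a in enumerate(ALPHABET):
        if label == Label.SHORT and a in HYDROPHOBIC:
            logits[i] += config.hydrophobic_shift
        if label == Label.LONG and a in ACIDIC:
            logits[i] += config.acidic_shift
    w = np.exp(logits)
    return w / w.sum()


def _draw_sequence(rng, comp: np.ndarray, length: int) -> list:
    idx = rng.choice(20, size=length, p=comp)
    return [ALPHABET[i] for i in idx]


def _plant_sp(rng, seq: list) -> Tuple[int, int]:
    """Overwrite the N-terminus with a signal-peptide-like cassette:
    M + basic n-region + 10-15 strongly hydrophobic h-region + polar c-region."""
    n_len = int(rng.integers(2, 5))
    h_len = int(rng.integers(10, 16))
    c_len = int(rng.integers(4, 7))
    n_pool, h_pool, c_pool = "KRNSA", "LIVF", "STAGQ"
    cassette = ["M"]
    n_region = [n_pool[i] for i in rng.integers(0, len(n_pool), n_len)]
    n_region[int(rng.integers(0, n_len))] = "KR"[int(rng.integers(0, 2))]
    cassette += n_region
    cassette += [h_pool[i] for i in rng.integers(0, len(h_pool), h_len)]
    cassette += [c_pool[i] for i in rng.integers(0, len(c_pool), c_len)]
    seq[:len(cassette)] = cassette
    return 0, len(cassette)


def _plant_tm(rng, seq: list, forbidden: List[Tuple[int, int]],
              max_tries: int = 20) -> Optional[Tuple[int, int]]:
    """Overwrite an interior stretch with a 19-25 residue hydrophobic helix."""
    tm_len = int(rng.integers(19, 26))
    L = len(seq)
    lo, hi = 5, L - tm_len - 5
    if hi <= lo:
        return None
    for _ in range(max_tries):
        start = int(rng.integers(lo, hi))
        span = (start, start + tm_len)
        if all(span[1] <= s or span[0] >= e for s, e in forbidden):
            pool = "LIVF"
            seq[span[0]:span[1]] = [pool[i] for i in
                                    rng.integers(0, 4, tm_len)]
            return span
    return None


def generate_proteome(config: Optional[GeneratorConfig] = None
                      ) -> Tuple[List[ProteinRecord], np.ndarray,
                                 List[PlantedCassette]]:
    """Generate (records, labels, truth_annotations); labels True = SHORT."""
    if config is None:
        config = GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    records: List[ProteinRecord] = []
    labels: List[bool] = []
    truth: List[PlantedCassette] = []
    specs = ([(Label.SHORT, i) for i in range(config.n_short)]
             + [(Label.LONG, i) for i in range(config.n_long)])
    comps = {lab: class_composition(config, lab) for lab in (Label.SHORT, Label.LONG)}
    for label, i in specs:
        short = label == Label.SHORT
        pid = f"{'S' if short else 'L'}{i:05d}"
        median = (config.length_median_short if short
                  else config.length_median_long)
        length = max(config.min_length,
                     int(rng.lognormal(np.log(median), config.length_sigma)))
        seq = _draw_sequence(rng, comps[label], length)
        occupied: List[Tuple[int, int]] = []
        p_sp = config.p_sp_short if short else config.p_sp_long
        if rng.random() < p_sp:
            span = _plant_sp(rng, seq)
            occupied.append(span)
            truth.append(PlantedCassette(pid, "SP", *span))
        p_tm = config.p_tm_short if short else config.p_tm_long
        if rng.random() < p_tm:
            for _ in range(int(rng.integers(1, 4))):
                span = _plant_tm(rng, seq, occupied)
                if span is not None:
                    occupied.append(span)
                    truth.append(PlantedCassette(pid, "TM", *span))
        if short:
            psi = 2.0
            while psi >= 2.0:
                psi = rng.lognormal(np.log(1.2), 0.25)
        else:
            psi = 0.0
            while psi < 2.0:
                psi = rng.lognormal(np.log(4.5), 0.4)
        records.append(ProteinRecord(id=pid, sequence="".join(seq),
                                     psi=float(psi), label=label))
        labels.append(short)
    return records, np.array(labels, dtype=bool), truth


def write_truth_table(truth: Sequence[PlantedCassette], path) -> None:
    """BED-like truth table of planted cassettes (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("record\tstart\tend\tkind\n")
        for c in truth:
            fh.write(f"{c.record_id}\t{c.start}\t{c.end}\t{c.kind}\n")


def write_proteome(records, truth, outdir) -> dict:
    """Write FASTA + PSI table + truth annotations; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"fasta": outdir / "proteome.fasta",
             "psi": outdir / "psi.tsv",
             "truth": outdir / "truth.tsv"}
    write_fasta(records, paths["fasta"])
    write_psi_table(records, paths["psi"])
    write_truth_table(truth, paths["truth"])
    return paths


def truth_check(records: Sequence[ProteinRecord],
                truth: Sequence[PlantedCassette]) -> dict:
    """Detector recall on planted cassettes (the extractors' recall oracle).

    Reports the fraction of planted SP cassettes detected by the default
    signal-peptide heuristic, the fraction of planted TM cassettes whose
    span overlaps a detected TM region by >= 50%, and the SP
    false-positive rate on records with no planted SP cassette.
    """
    from .features_motifs import predict_signal_peptide, predict_tm

    by_id = {r.id: r for r in records}
    sp_ids = {c.record_id for c in truth if c.kind == "SP"}
    sp_hits = sum(predict_signal_peptide(by_id[i].sequence) for i in sp_ids)
    tm_cassettes = [c for c in truth if c.kind == "TM"]
    tm_hits = 0
    tm_regions_cache: Dict[str, list] = {}
    for c in tm_cassettes:
        if c.record_id not in tm_regions_cache:
            _, _, regs = predict_tm(by_id[c.record_id].sequence)
            tm_regions_cache[c.record_id] = regs
        planted_len = c.end - c.start
        for r in tm_regions_cache[c.record_id]:
            overlap = min(c.end, r.end) - max(c.start, r.start)
            if overlap >= 0.5 * planted_len:
                tm_hits += 1
                break
    no_sp = [r for r in records if r.id not in sp_ids]
    fp = sum(predict_signal_peptide(r.sequence) for r in no_sp)
    return {
        "sp_recall": sp_hits / len(sp_ids) if sp_ids else float("nan"),
        "tm_recall": tm_hits / len(tm_cassettes) if tm_cassettes else float("nan"),
        "sp_false_positive_rate": fp / len(no_sp) if no_sp else float("nan"),
        "n_sp_planted": len(sp_ids),
        "n_tm_planted": len(tm_cassettes),
    }
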