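"""SOX monomer/dimer motif scanning and region-level motif classification.

A PWM is a log-odds matrix (log2 of position probability over a uniform
0.25 background), scanned over both strands of a sequence; windows scoring
at or above the PWM threshold are hits.  Regions are classified with a
precedence rule: a defined-dimer hit wins over a degenerate-dimer hit,
which wins over a monomer hit, counting only hits that do not overlap a
higher-precedence hit.  The shipped default motifs encode the SOXE
half-site (monomer) and the palindromic DNA-dependent dimer element.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GeneModel, GenomicInterval, Peak, ValidationError

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Default consensus motifs: the SOXE monomer half-site and the palindromic
# dimer element ACAAWGnnnnCWTTGT; the degenerate dimer relaxes the outer
# bases and the second half-site's C.
DEFAULT_CONSENSUS = {
    "monomer": "ACAAWG",
    "defined_dimer": "ACAAWGNNNNCWTTGT",
    "degenerate_dimer": "NCAAWGNNNNNWTTGN",
}
DEFAULT_THRESHOLD = 6.0


@dataclass(frozen=True)
class PWM:
    """Log-odds position weight matrix over A,C,G,T with a hit threshold."""

    name: str
    log_odds: np.ndarray  # shape (L, 4)
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        lo = np.asarray(self.log_odds, dtype=float)
        if lo.ndim != 2 or lo.shape[1] != 4 or lo.shape[0] < 1:
            raise ValidationError("log_odds must be an L x 4 matrix with L >= 1")
        if not np.all(np.isfinite(lo)):
            raise ValidationError("log_odds entries must be finite")
        object.__setattr__(self, "log_odds", lo)

    def __len__(self) -> int:
        return self.log_odds.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    strand: str
    score: float
    motif: str


class MotifClass(enum.Enum):
    DEFINED_DIMER = "defined_dimer"
    DEGENERATE_DIMER = "degenerate_dimer"
    MONOMER_ONLY = "monomer_only"
    NONE = "none"


def pwm_from_consensus(
    iupac: str,
    name: str = "consensus",
    match_prob: float = 0.997,
    threshold: float = DEFAULT_THRESHOLD,
) -> PWM:
    """Build a PWM from an IUPAC consensus.

    Per position, the allowed bases share ``match_prob`` equally and the
    disallowed bases share the remainder; N columns are uniform (log-odds 0).
    """
    if not (0.25 < match_prob < 1):
        raise ValidationError("match_prob must be in (0.25, 1)")
    iupac = iupac.upper()
    probs = np.empty((len(iupac), 4), dtype=float)
    for i, code in enumerate(iupac):
        try:
            allowed = IUPAC[code]
        except KeyError:
            raise ValidationError(f"unknown IUPAC code {code!r}") from None
        if len(allowed) == 4:
            probs[i] = 0.25
            continue
        p_in = match_prob / len(allowed)
        p_out = (1 - match_prob) / (4 - len(allowed))
        for base, j in _BASE_INDEX.items():
            probs[i, j] = p_in if base in allowed else p_out
    return PWM(name, np.log2(probs / 0.25), threshold)


def default_pwms(match_prob: float = 0.997) -> dict[str, PWM]:
    return {
        name: pwm_from_consensus(cons, name=name, match_prob=match_prob)
        for name, cons in DEFAULT_CONSENSUS.items()
    }


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3 and N (or any other code) -> 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _window_scores(encoded: np.ndarray, pwm: PWM) -> np.ndarray:
    """Score of every length-L window; N bases contribute 0 (background)."""
    L = len(pwm)
    n = encoded.size - L + 1
    if n <= 0:
        return np.empty(0, dtype=float)
    lom = np.concatenate([pwm.log_odds, np.zeros((L, 1))], axis=1)  # N column
    scores = np.zeros(n, dtype=float)
    for j in range(L):
        scores += lom[j, encoded[j : j + n]]
    return scores


def scan(
    sequence: str,
    pwm: PWM,
    chrom: str = "seq",
    offset: int = 0,
) -> list[MotifHit]:
    """Scan both strands; report hits with score >= threshold on the forward axis.

    A minus-strand hit at reverse-complement position i maps to forward
    interval [n - i - L, n - i).  Hits are sorted by (start, strand).
    """
    seq = sequence.upper()
    n, L = len(seq), len(pwm)
    hits: list[MotifHit] = []
    if n < L:
        return hits
    fwd = _window_scores(_encode(seq), pwm)
    rev = _window_scores(_encode(reverse_complement(seq)), pwm)
    for i in np.nonzero(fwd >= pwm.threshold)[0]:
        hits.append(
            MotifHit(
                GenomicInterval(chrom, offset + int(i), offset + int(i) + L),
                "+",
                float(fwd[i]),
                pwm.name,
            )
        )
    for i in np.nonzero(rev >= pwm.threshold)[0]:
        start = offset + n - int(i) - L
        hits.append(
            MotifHit(GenomicInterval(chrom, start, start + L), "-", float(rev[i]), pwm.name)
        )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def _overlaps_any(hit: MotifHit, others: Iterable[MotifHit]) -> bool:
    return any(hit.interval.overlaps(o.interval) for o in others)


def classify_region_motifs(
    defined_hits: Sequence[MotifHit],
    degenerate_hits: Sequence[MotifHit],
    monomer_hits: Sequence[MotifHit],
) -> MotifClass:
    """Precedence classification of one region's motif content.

    Degenerate-dimer occurrences overlapping a defined-dimer hit are not
    counted, and monomer occurrences overlapping either dimer's hits are
    not counted (>=1 shared base on either strand).
    """
    if defined_hits:
        return MotifClass.DEFINED_DIMER
    if any(not _overlaps_any(h, defined_hits) for h in degenerate_hits):
        return MotifClass.DEGENERATE_DIMER
    dimer_hits = list(defined_hits) + list(degenerate_hits)
    if any(not _overlaps_any(h, dimer_hits) for h in monomer_hits):
        return MotifClass.MONOMER_ONLY
    return MotifClass.NONE


def classify_sequence(
    sequence: str, pwms: Mapping[str, PWM] | None = None
) -> MotifClass:
    """Scan one region sequence with the three motif PWMs and classify it."""
    pwms = pwms or default_pwms()
    return classify_region_motifs(
        scan(sequence, pwms["defined_dimer"]),
        scan(sequence, pwms["degenerate_dimer"]),
        scan(sequence, pwms["monomer"]),
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a {name: sequence} mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def classify_peak_regions(
    peaks: Sequence[Peak],
    genome: Mapping[str, str],
    pwms: Mapping[str, PWM] | None = None,
    scan_half: int = 150,
) -> tuple[list[MotifHit], pd.DataFrame]:
    """Scan the summit +/- ``scan_half`` window of each peak and classify it.

    Returns all hits (genome coordinates) and a frame with one motif class
    per region (columns name, chrom, summit, motif_class).
    """
    pwms = pwms or default_pwms()
    all_hits: list[MotifHit] = []
    rows = []
    for peak in peaks:
        chrom = peak.interval.chrom
        seq = genome[chrom]
        start = max(0, peak.summit - scan_half)
        window = seq[start : peak.summit + scan_half]
        per_motif = {
            name: scan(window, pwm, chrom=chrom, offset=start)
            for name, pwm in pwms.items()
        }
        cls = classify_region_motifs(
            per_motif.get("defined_dimer", []),
            per_motif.get("degenerate_dimer", []),
            per_motif.get("monomer", []),
        )
        for hits in per_motif.values():
            all_hits.extend(hits)
        rows.append(
            {
                "name": peak.name,
                "chrom": chrom,
                "summit": peak.summit,
                "motif_class": cls.value,
            }
        )
    all_hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.strand))
    return all_hits, pd.DataFrame(rows, columns=["name", "chrom", "summit", "motif_class"])


# ---------------------------------------------------------------------------
# PWM text format: header line ">name threshold", then L rows of 4 probabilities


def read_pwm(path: str | Path) -> PWM:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith(">"):
            raise ValidationError(f"{path}: PWM file must start with '>name threshold'")
        parts = header[1:].split()
        name = parts[0]
        threshold = float(parts[1]) if len(parts) > 1 else DEFAULT_THRESHOLD
        rows = []
        for line in fh:
            if not line.strip():
                continue
            vals = [float(x) for x in line.split()]
            if len(vals) != 4:
                raise ValidationError(f"{path}: each PWM row needs 4 probabilities")
            if abs(sum(vals) - 1.0) > 1e-6 or min(vals) <= 0:
                raise ValidationError(
                    f"{path}: probabilities must be positive and sum to 1"
                )
            rows.append(vals)
    probs = np.array(rows, dtype=float)
    return PWM(name, np.log2(probs / 0.25), threshold)


def write_pwm(pwm: PWM, path: str | Path) -> None:
    probs = 0.25 * np.exp2(pwm.log_odds)
    with open(path, "w") as fh:
        fh.write(f">{pwm.name} {pwm.threshold:g}\n")
        for row in probs:
            fh.write("\t".join(f"{x:.6g}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# region-to-gene association and direct-target calling


def associate_regions_to_genes(
    regions: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    max_distance: int = 100_000,
) -> pd.DataFrame:
    """Map each region to the gene(s) with nearest TSS within ``max_distance``.

    Distance is from the region midpoint to the TSS.  Exact ties map the
    region to every tied gene and set the ``tied`` flag.  Unmapped regions
    are omitted.  Returns columns region, gene_id, distance, tied.
    """
    rows = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    for region in regions:
        candidates = by_chrom.get(region.chrom, [])
        if not candidates:
            continue
        mid = (region.start + region.end) // 2
        dists = [(abs(g.tss - mid), g) for g in candidates]
        best = min(d for d, _ in dists)
        if best > max_distance:
            continue
        tied = [g for d, g in dists if d == best]
        for g in sorted(tied, key=lambda g: g.gene_id):
            rows.append(
                {
                    "chrom": region.chrom,
                    "start": region.start,
                    "end": region.end,
                    "gene_id": g.gene_id,
                    "distance": best,
                    "tied": len(tied) > 1,
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene_id", "distance", "tied"]
    )


def call_direct_targets(
    mapping: pd.DataFrame,
    expression: Mapping[str, float] | pd.Series,
    min_abs_log2: float = 0.5,
) -> tuple[list[str], list[str]]:
    """Split mapped genes into up/down direct targets by expression log2 ratio.

    A gene qualifies when its |log2 ratio| exceeds ``min_abs_log2`` (strict,
    so a ratio of exactly 0.5 is not a target).  Genes absent from the
    expression table are ignored.  Returns sorted (up, down) gene lists.
    """
    expr = pd.Series(expression, dtype=float)
    mapped = sorted(set(mapping["gene_id"]) & set(expr.index))
    up = [g for g in mapped if expr[g] > min_abs_log2]
    down = [g for g in mapped if expr[g] < -min_abs_log2]
    return up, down
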