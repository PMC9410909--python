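"""Two-condition synthetic datasets with planted ground truth.

Every analysis stage in this package is exercised against data whose truth
is known by construction: chromatin-state plans with condition switches,
binned accessibility with planted fold changes (including confounded bins
that carry a pre-existing peak, to exercise the peak-absence filter),
summit-centered multi-track profiles with four planted binding-mode
signatures, sequences with planted SOX monomer/dimer motifs, and fragment
files with planted length regimes.

Noise is multiplicative log-normal (exp of N(0, noise_sd^2)) on signal
means, keeping coverage strictly positive with a controllable relative
error.  Each output file draws from its own pseudo-random stream derived
from (seed, file tag), so adding one output never perturbs the others.
Identical configs produce byte-identical files.

Planted regions are spaced 10 kb apart so summit windows never overlap.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_io import (
    Fragment,
    GeneModel,
    GenomicInterval,
    Peak,
    write_fragments,
    write_genes,
    write_peaks,
    write_tsv,
)
from .motif_scan import MotifClass, classify_sequence, default_pwms

STATES = ("active", "primed", "quiescent", "repressed")
STATE_MARKS = {
    "active": ("k4me1", "k27ac"),
    "primed": ("k4me1",),
    "repressed": ("k27me3",),
    "quiescent": (),
}
CLUSTERS = ("C1", "C2", "C3", "C4")

SPACING = 10_000
MARGIN = 5_000
PEAK_SCORE = 10.0  # -log10 p; comfortably past the p < 1e-5 filter


@dataclass
class SimulationConfig:
    """Study conditions for all four generators; defaults are the test bed.

    noise_sd is the s.d. of the log-normal multiplicative noise (natural-log
    scale).  high_level / low_level are chosen so the planted binding-mode
    signatures sit >= 5 noise-s.d. apart at the default noise_sd = 0.4
    (ln(8/1) / 0.4 = 5.2).
    """

    seed: int = 0
    # chromatin states
    n_state_regions: int = 200
    # accessibility
    n_bins_diff: int = 10_000
    bin_size: int = 1000
    n_increased: int = 100
    n_decreased: int = 100
    n_confounded: int = 100
    baseline_mean: float = 10.0
    fold_change: float = 4.0
    noise_sd: float = 0.0
    # binding modes
    n_per_cluster: int = 100
    low_level: float = 1.0
    high_level: float = 8.0
    mode_noise_sd: float = 0.0
    monomer_fraction: float = 0.5
    # fragments
    n_direct_foci: int = 10
    n_nucleosomal_foci: int = 10
    fragments_per_focus: int = 1000
    direct_mu: float = 80.0
    nucleosomal_mu: float = 150.0
    fragment_sd: float = 10.0


def stream(config: SimulationConfig, tag: str) -> np.random.Generator:
    """Independent RNG stream for one output file, derived from (seed, tag)."""
    return np.random.default_rng([config.seed, zlib.crc32(tag.encode())])


def _region_centers(n: int, spacing: int = SPACING, margin: int = MARGIN) -> np.ndarray:
    return margin + spacing * np.arange(n, dtype=np.int64)


def _lognormal_noise(rng: np.random.Generator, sd: float, size) -> np.ndarray:
    if sd <= 0:
        return np.ones(size)
    return np.exp(rng.normal(0.0, sd, size=size))


# ---------------------------------------------------------------------------
# chromatin states


def simulate_state_dataset(
    config: SimulationConfig,
    outdir: str | Path,
    state_plan: Sequence[tuple[str, str]] | None = None,
) -> dict[str, Path]:
    """Peak files for three marks x two conditions plus the state truth table.

    For each planted region the condition-specific peaks exist exactly for
    the marks its state implies; summits sit at region centers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = config.n_state_regions
    if state_plan is None:
        rng = stream(config, "state_plan")
        state_plan = [
            (STATES[i], STATES[j])
            for i, j in zip(rng.integers(0, 4, n), rng.integers(0, 4, n))
        ]
    else:
        for sa, sb in state_plan:
            if sa not in STATE_MARKS or sb not in STATE_MARKS:
                raise ValueError(f"unknown state in plan: ({sa}, {sb})")
        n = len(state_plan)
    centers = _region_centers(n)
    paths: dict[str, Path] = {}
    for cond_idx, cond in enumerate(("condA", "condB")):
        for mark in ("k4me1", "k27ac", "k27me3"):
            peaks = []
            for i, c in enumerate(centers):
                state = state_plan[i][cond_idx]
                if mark in STATE_MARKS[state]:
                    iv = GenomicInterval("chr1", int(c) - 300, int(c) + 300)
                    peaks.append(Peak(iv, int(c), PEAK_SCORE, f"{mark}_{cond}_{i}"))
            path = outdir / f"{mark}_{cond}.narrowPeak"
            write_peaks(peaks, path)
            paths[f"{mark}_{cond}"] = path
    truth = outdir / "truth_states.tsv"
    write_tsv(
        (
            ("chr1", int(c) - 500, int(c) + 500, sa, sb)
            for c, (sa, sb) in zip(centers, state_plan)
        ),
        truth,
        header=("chrom", "start", "end", "state_a", "state_b"),
    )
    paths["truth"] = truth
    return paths


# ---------------------------------------------------------------------------
# accessibility


def simulate_accessibility(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Binned two-condition accessibility tracks with planted fold changes.

    Planted classes per 1-kb bin: "increased" (condB = fold x condA, no
    condA peak), "decreased" (condB = condA / fold, no condB peak),
    "confounded" (fold change up but a condA ATAC peak is present, so the
    caller must exclude it), and "unchanged".  Log-normal noise multiplies
    each bin mean independently per condition.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n, bs = config.n_bins_diff, config.bin_size
    n_special = config.n_increased + config.n_decreased + config.n_confounded
    if n_special > n:
        raise ValueError("more planted bins than bins")
    rng_plan = stream(config, "accessibility_plan")
    order = rng_plan.permutation(n)
    classes = np.array(["unchanged"] * n, dtype=object)
    i0 = 0
    for cls, cnt in (
        ("increased", config.n_increased),
        ("decreased", config.n_decreased),
        ("confounded", config.n_confounded),
    ):
        classes[order[i0 : i0 + cnt]] = cls
        i0 += cnt

    f = config.fold_change
    mean_a = np.full(n, config.baseline_mean)
    mean_b = np.full(n, config.baseline_mean)
    mean_b[classes == "increased"] *= f
    mean_b[classes == "confounded"] *= f
    mean_b[classes == "decreased"] /= f
    noisy_a = mean_a * _lognormal_noise(stream(config, "atac_condA"), config.noise_sd, n)
    noisy_b = mean_b * _lognormal_noise(stream(config, "atac_condB"), config.noise_sd, n)

    paths: dict[str, Path] = {}
    for cond, vals in (("condA", noisy_a), ("condB", noisy_b)):
        path = outdir / f"atac_{cond}.bedGraph"
        with open(path, "w") as fh:
            for b in range(n):
                fh.write(f"chr1\t{b * bs}\t{(b + 1) * bs}\t{vals[b]:.6g}\n")
        paths[f"atac_{cond}"] = path

    def bin_peak(b: int, tag: str) -> Peak:
        iv = GenomicInterval("chr1", b * bs, (b + 1) * bs)
        return Peak(iv, b * bs + bs // 2, PEAK_SCORE, f"{tag}_{b}")

    peaks_a = [bin_peak(b, "a") for b in np.nonzero((classes == "confounded") | (classes == "decreased"))[0]]
    peaks_b = [bin_peak(b, "b") for b in np.nonzero((classes == "increased") | (classes == "confounded"))[0]]
    paths["peaks_condA"] = outdir / "atac_peaks_condA.narrowPeak"
    paths["peaks_condB"] = outdir / "atac_peaks_condB.narrowPeak"
    write_peaks(peaks_a, paths["peaks_condA"])
    write_peaks(peaks_b, paths["peaks_condB"])

    truth = outdir / "truth_accessibility.tsv"
    write_tsv(
        (
            ("chr1", b * bs, (b + 1) * bs, classes[b], f"{mean_b[b] / mean_a[b]:g}",
             "yes" if classes[b] == "confounded" else "no")
            for b in range(n)
        ),
        truth,
        header=("chrom", "start", "end", "class", "planted_fold", "excluded"),
    )
    paths["truth"] = truth
    return paths


# ---------------------------------------------------------------------------
# binding modes + motifs

# (condA level, condB level) per track, as multiples of (low, high)
_MODE_SIGNATURES: dict[str, dict[str, tuple[str, str]]] = {
    "C1": {"atac": ("H", "H"), "k4me1": ("H", "H"), "k27ac": ("H", "H"),
           "k27me3": ("L", "L"), "tf": ("L", "H")},
    "C2": {"atac": ("L", "H"), "k4me1": ("L", "H"), "k27ac": ("L", "H"),
           "k27me3": ("L", "L"), "tf": ("L", "H")},
    "C3": {"atac": ("L", "L"), "k4me1": ("L", "L"), "k27ac": ("L", "L"),
           "k27me3": ("H", "H"), "tf": ("L", "H")},
    "C4": {"atac": ("L", "L"), "k4me1": ("L", "L"), "k27ac": ("L", "L"),
           "k27me3": ("L", "L"), "tf": ("L", "H")},
}
MODE_TRACKS = [
    f"{t}_{c}" for t in ("tf", "atac", "k4me1", "k27ac", "k27me3")
    for c in ("condA", "condB")
]
_BASES = np.array(list("ACGT"))
SCAN_HALF = 150  # motif scan window: summit +/- 150 bp (300 bp)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _motif_instance(rng: np.random.Generator, motif_class: MotifClass) -> str:
    w = lambda: "AT"[rng.integers(0, 2)]
    any_base = lambda: "ACGT"[rng.integers(0, 4)]
    if motif_class is MotifClass.MONOMER_ONLY:
        return "ACAA" + w() + "G"
    if motif_class is MotifClass.DEFINED_DIMER:
        return "ACAA" + w() + "G" + "".join(any_base() for _ in range(4)) + "C" + w() + "TTGT"
    if motif_class is MotifClass.DEGENERATE_DIMER:
        # mismatch the defined dimer at its three constrained outer positions
        p1 = "CGT"[rng.integers(0, 3)]
        p11 = "AGT"[rng.integers(0, 3)]
        p16 = "ACG"[rng.integers(0, 3)]
        return (p1 + "CAA" + w() + "G" + "".join(any_base() for _ in range(4))
                + p11 + w() + "TTG" + p16)
    return ""


def _planted_window(
    rng: np.random.Generator, motif_class: MotifClass, width: int, pwms, max_tries: int = 200
) -> str:
    """A scan-window sequence whose motif classification equals the plan.

    Rejection sampling: random background plus the planted instance at the
    window center, regenerated until the scanner-derived class matches (a
    chance background hit of a different class triggers a resample).
    """
    instance = _motif_instance(rng, motif_class)
    for _ in range(max_tries):
        seq = _random_seq(rng, width)
        if instance:
            mid = (width - len(instance)) // 2
            seq = seq[:mid] + instance + seq[mid + len(instance):]
        if classify_sequence(seq, pwms) is motif_class:
            return seq
    raise RuntimeError(f"could not plant {motif_class} in {max_tries} tries")


def simulate_mode_dataset(
    config: SimulationConfig,
    outdir: str | Path,
    mode_plan: Sequence[str] | None = None,
    motif_plan: Sequence[MotifClass] | None = None,
) -> dict[str, Path]:
    """TF peaks, ten signal tracks, a genome FASTA and the mode/motif truth.

    Each TF summit's 4-kb window carries per-track constant mean levels
    from its planted cluster signature (C1: open in both conditions; C2:
    opened in condB only; C3: H3K27me3-high; C4: low everywhere), with
    multiplicative log-normal noise per 100-bp sub-run.  Sequences receive
    planted motifs: the defined dimer in C1/C2, a monomer in a configurable
    fraction of C3/C4, background elsewhere.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if mode_plan is None:
        rng = stream(config, "mode_plan")
        plan = np.repeat(CLUSTERS, config.n_per_cluster)
        mode_plan = list(plan[rng.permutation(plan.size)])
    n = len(mode_plan)
    if motif_plan is None:
        rng = stream(config, "motif_plan")
        motif_plan = []
        for cluster in mode_plan:
            if cluster in ("C1", "C2"):
                motif_plan.append(MotifClass.DEFINED_DIMER)
            elif rng.random() < config.monomer_fraction:
                motif_plan.append(MotifClass.MONOMER_ONLY)
            else:
                motif_plan.append(MotifClass.NONE)
    centers = _region_centers(n)
    chrom_len = int(centers[-1]) + MARGIN
    levels = {"L": config.low_level, "H": config.high_level}
    paths: dict[str, Path] = {}

    # TF peaks
    tf_peaks = [
        Peak(
            GenomicInterval("chr1", int(c) - 250, int(c) + 250),
            int(c),
            PEAK_SCORE,
            f"region_{i:04d}",
        )
        for i, c in enumerate(centers)
    ]
    paths["tf_peaks"] = outdir / "tf_peaks.narrowPeak"
    write_peaks(tf_peaks, paths["tf_peaks"])

    # signal tracks: 100-bp sub-runs across each 4-kb window
    sub = 100
    n_sub = 4000 // sub
    for name in MODE_TRACKS:
        track_base, cond = name.rsplit("_", 1)
        cond_idx = 0 if cond == "condA" else 1
        rng = stream(config, f"track_{name}")
        path = outdir / f"{name}.bedGraph"
        with open(path, "w") as fh:
            for i, c in enumerate(centers):
                level = levels[_MODE_SIGNATURES[mode_plan[i]][track_base][cond_idx]]
                noise = _lognormal_noise(rng, config.mode_noise_sd, n_sub)
                w_start = int(c) - 2000
                for s in range(n_sub):
                    fh.write(
                        f"chr1\t{w_start + s * sub}\t{w_start + (s + 1) * sub}\t"
                        f"{level * noise[s]:.6g}\n"
                    )
        paths[name] = path

    # genome FASTA with planted motifs in each scan window (summit +/- 150)
    rng_seq = stream(config, "genome")
    pwms = default_pwms()
    seq = list(_random_seq(rng_seq, chrom_len))
    for i, c in enumerate(centers):
        window = _planted_window(rng_seq, motif_plan[i], 2 * SCAN_HALF, pwms)
        seq[int(c) - SCAN_HALF : int(c) + SCAN_HALF] = window
    paths["fasta"] = outdir / "genome.fa"
    with open(paths["fasta"], "w") as fh:
        fh.write(">chr1\n")
        s = "".join(seq)
        for i in range(0, len(s), 80):
            fh.write(s[i : i + 80] + "\n")

    truth = outdir / "truth_modes.tsv"
    write_tsv(
        (
            (
                f"region_{i:04d}", "chr1", int(c) - 2000, int(c) + 2000, int(c),
                mode_plan[i], motif_plan[i].value,
            )
            for i, c in enumerate(centers)
        ),
        truth,
        header=("name", "chrom", "start", "end", "summit", "cluster", "motif_class"),
    )
    paths["truth"] = truth
    return paths


def simulate_genes(
    config: SimulationConfig, outdir: str | Path, mode_plan: Sequence[str] | None = None
) -> dict[str, Path]:
    """One gene near each binding-mode region plus an expression table.

    Genes start 1-4 kb downstream of their region's summit (well within
    the 100-kb association cap) on a random strand.  Genes tied to C1/C2
    regions are
    planted as up-regulated (log2 ratio ~ N(1.5, 0.3)); C3/C4 genes stay
    near zero (N(0, 0.2)).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if mode_plan is None:
        rng = stream(config, "mode_plan")
        plan = np.repeat(CLUSTERS, config.n_per_cluster)
        mode_plan = list(plan[rng.permutation(plan.size)])
    n = len(mode_plan)
    centers = _region_centers(n)
    rng = stream(config, "genes")
    genes, expr_rows = [], []
    for i, c in enumerate(centers):
        offset = int(rng.integers(1000, 4000))
        strand = "+-"[rng.integers(0, 2)]
        start = int(c) + offset
        genes.append(
            GeneModel(f"gene_{i:04d}", GenomicInterval("chr1", start, start + 2000, strand))
        )
        if mode_plan[i] in ("C1", "C2"):
            ratio = rng.normal(1.5, 0.3)
        else:
            ratio = rng.normal(0.0, 0.2)
        expr_rows.append((f"gene_{i:04d}", f"{ratio:.4f}", mode_plan[i]))
    paths = {
        "genes": Path(outdir) / "genes.tsv",
        "expression": Path(outdir) / "expression.tsv",
    }
    write_genes(genes, paths["genes"])
    write_tsv(expr_rows, paths["expression"], header=("gene_id", "log2_ratio", "cluster"))
    return paths


# ---------------------------------------------------------------------------
# fragments


def simulate_fragments(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Fragment BED with planted foci in two length regimes, plus peaks.

    Fragments are centered on each planted focus with lengths drawn from
    Normal(mu, sigma) truncated at >= 20 bp: "direct" foci use mu < 100,
    "nucleosomal" foci mu > 120.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plans = [("direct", config.direct_mu)] * config.n_direct_foci + [
        ("nucleosomal", config.nucleosomal_mu)
    ] * config.n_nucleosomal_foci
    centers = _region_centers(len(plans))
    rng = stream(config, "fragments")
    fragments, truth_rows, peaks = [], [], []
    for i, ((mode, mu), c) in enumerate(zip(plans, centers)):
        lengths = np.maximum(
            20, np.rint(rng.normal(mu, config.fragment_sd, config.fragments_per_focus))
        ).astype(np.int64)
        for ln in lengths:
            start = int(c) - int(ln) // 2
            fragments.append(Fragment(GenomicInterval("chr1", start, start + int(ln))))
        peaks.append(
            Peak(
                GenomicInterval("chr1", int(c) - 500, int(c) + 500),
                int(c),
                PEAK_SCORE,
                f"focus_{i:02d}",
            )
        )
        truth_rows.append(
            ("chr1", int(c), f"focus_{i:02d}", mode, f"{mu:g}",
             f"{config.fragment_sd:g}", config.fragments_per_focus)
        )
    fragments.sort(key=lambda fr: (fr.interval.start, fr.interval.end))
    paths = {
        "fragments": Path(outdir) / "fragments.bed",
        "peaks": Path(outdir) / "fragment_peaks.narrowPeak",
        "truth": Path(outdir) / "truth_foci.tsv",
    }
    write_fragments(fragments, paths["fragments"])
    write_peaks(peaks, paths["peaks"])
    write_tsv(
        truth_rows,
        paths["truth"],
        header=("chrom", "position", "name", "mode", "mu", "sigma", "n_fragments"),
    )
    return paths


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Run every generator into subdirectories of ``outdir``."""
    outdir = Path(outdir)
    paths = {}
    paths.update({f"states/{k}": v for k, v in simulate_state_dataset(config, outdir / "states").items()})
    paths.update({f"accessibility/{k}": v for k, v in simulate_accessibility(config, outdir / "accessibility").items()})
    paths.update({f"modes/{k}": v for k, v in simulate_mode_dataset(config, outdir / "modes").items()})
    paths.update({f"genes/{k}": v for k, v in simulate_genes(config, outdir / "modes").items()})
    paths.update({f"fragments/{k}": v for k, v in simulate_fragments(config, outdir / "fragments").items()})
    return paths
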