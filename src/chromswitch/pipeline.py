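"""End-to-end orchestration with a single config and a reproducibility manifest.

Stages run in dependency order: simulate -> states -> diffacc -> modes ->
motifs -> echo -> targets.  When simulation is enabled its outputs feed the
downstream stages; otherwise each enabled stage must name its input files
in the config.  The manifest records the config hash, package version and a
sha256 checksum per output file (no timestamps), so a rerun with an
identical config reproduces an identical manifest byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .binding_modes import average_signal, cluster_modes, extract_matrix, label_clusters
from .chromatin_states import (
    GeneAnnotator,
    build_region_universe,
    call_states,
    compute_transitions,
    count_changed,
)
from .core_io import (
    ValidationError,
    read_fragments,
    read_genes,
    read_peaks,
    read_signal,
    write_bed,
    write_tsv,
)
from .diff_accessibility import binned_log2_ratio, call_differential
from .fragment_echo import find_all_foci
from .motif_scan import (
    associate_regions_to_genes,
    call_direct_targets,
    classify_peak_regions,
    default_pwms,
    read_fasta,
    read_pwm,
)
from .synthetic_data import MODE_TRACKS, SimulationConfig, simulate_all

STAGES = ("states", "diffacc", "modes", "motifs", "echo", "targets")


class ConfigError(ValueError):
    """Pipeline config invalid; message names the offending key."""


@dataclass
class PipelineConfig:
    seed: int
    outdir: Path
    simulate: bool = True
    sim: SimulationConfig = None
    stages: dict[str, bool] = field(default_factory=dict)
    params: dict[str, Any] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = SimulationConfig(seed=self.seed)
        for stage in STAGES:
            self.stages.setdefault(stage, True)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        if "seed" not in raw:
            raise ConfigError("config missing required key `seed`")
        if "outdir" not in raw:
            raise ConfigError("config missing required key `outdir`")
        sim_kwargs = dict(raw.get("sim", {}))
        sim_kwargs.setdefault("seed", raw["seed"])
        try:
            sim = SimulationConfig(**sim_kwargs)
        except TypeError as exc:
            raise ConfigError(f"bad `sim` section: {exc}") from None
        return cls(
            seed=int(raw["seed"]),
            outdir=Path(raw["outdir"]),
            simulate=bool(raw.get("simulate", True)),
            sim=sim,
            stages=dict(raw.get("stages", {})),
            params=dict(raw.get("params", {})),
            inputs=dict(raw.get("inputs", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(raw)

    def require_inputs(self, stage: str, keys: list[str]) -> None:
        missing = [k for k in keys if k not in self.inputs]
        if missing:
            raise ConfigError(
                f"stage `{stage}` enabled without simulation but config lacks "
                f"input(s): {', '.join(missing)}"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        {
            "seed": config.seed,
            "simulate": config.simulate,
            "sim": vars(config.sim),
            "stages": config.stages,
            "params": config.params,
            "inputs": config.inputs,
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run enabled stages, write per-stage outputs and the manifest.

    Returns a summary dict with per-stage headline numbers (also written
    as ``summary.json``).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config_hash = _config_hash(config)  # before simulation fills in input paths
    params = config.params
    summary: dict[str, Any] = {}
    produced: list[Path] = []

    if config.simulate:
        sim_paths = simulate_all(config.sim, out / "simulated")
        inputs = {k: str(v) for k, v in sim_paths.items()}
        produced.extend(sim_paths.values())
        # map simulated files onto the stage input keys
        config.inputs = {
            **{
                f"{m}_{c}": inputs[f"states/{m}_{c}"]
                for m in ("k4me1", "k27ac", "k27me3")
                for c in ("condA", "condB")
            },
            "atac_track_condA": inputs["accessibility/atac_condA"],
            "atac_track_condB": inputs["accessibility/atac_condB"],
            "atac_peaks_condA": inputs["accessibility/peaks_condA"],
            "atac_peaks_condB": inputs["accessibility/peaks_condB"],
            "tf_peaks": inputs["modes/tf_peaks"],
            **{f"track_{t}": inputs[f"modes/{t}"] for t in MODE_TRACKS},
            "genome_fasta": inputs["modes/fasta"],
            "genes": inputs["genes/genes"],
            "expression": inputs["genes/expression"],
            "fragments": inputs["fragments/fragments"],
            "fragment_peaks": inputs["fragments/peaks"],
        }

    p_threshold = params.get("p_threshold", 1e-5)
    genes = None
    if config.stages.get("states") or config.stages.get("targets"):
        config.require_inputs("states", ["genes"])
        genes = read_genes(config.inputs["genes"])

    if config.stages.get("states"):
        keys = [
            f"{m}_{c}" for m in ("k4me1", "k27ac", "k27me3") for c in ("condA", "condB")
        ]
        config.require_inputs("states", keys)
        peaks = {k: read_peaks(config.inputs[k], p_threshold) for k in keys}
        universe = build_region_universe(list(peaks.values()))
        annot = GeneAnnotator(genes)
        calls = {}
        for cond in ("condA", "condB"):
            calls[cond] = call_states(
                universe,
                {m: peaks[f"{m}_{cond}"] for m in ("k4me1", "k27ac", "k27me3")},
                cond,
                annot,
                fold_other_into_active=params.get("fold_other_into_active", False),
            )
        transitions = compute_transitions(calls["condA"], calls["condB"])
        sdir = out / "states"
        sdir.mkdir(exist_ok=True)
        write_tsv(
            (
                (
                    a.region.chrom, a.region.start, a.region.end,
                    a.state.value, b.state.value, a.compartment,
                    int(a.multi_match), int(b.multi_match),
                )
                for a, b in zip(calls["condA"], calls["condB"])
            ),
            sdir / "state_calls.tsv",
            header=(
                "chrom", "start", "end", "state_a", "state_b", "compartment",
                "multi_match_a", "multi_match_b",
            ),
        )
        transitions.to_csv(sdir / "transitions.tsv", sep="\t", index=False)
        produced += [sdir / "state_calls.tsv", sdir / "transitions.tsv"]
        summary["states"] = {
            "n_regions": len(universe),
            "n_changed": count_changed(transitions),
        }

    if config.stages.get("diffacc"):
        config.require_inputs(
            "diffacc",
            ["atac_track_condA", "atac_track_condB", "atac_peaks_condA", "atac_peaks_condB"],
        )
        track_a = read_signal(config.inputs["atac_track_condA"])
        track_b = read_signal(config.inputs["atac_track_condB"])
        changes = binned_log2_ratio(
            track_a,
            track_b,
            bin_size=params.get("bin_size", 1000),
            pseudocount=params.get("pseudocount", 1.0),
        )
        inc, dec, annotated = call_differential(
            changes,
            read_peaks(config.inputs["atac_peaks_condA"], p_threshold),
            read_peaks(config.inputs["atac_peaks_condB"], p_threshold),
            fold=params.get("fold", 2.0),
        )
        ddir = out / "diffacc"
        ddir.mkdir(exist_ok=True)
        write_bed(inc, ddir / "increased.bed")
        write_bed(dec, ddir / "decreased.bed")
        write_tsv(
            (
                (
                    ch.bin.chrom, ch.bin.start, ch.bin.end,
                    f"{ch.mean_a:.6g}", f"{ch.mean_b:.6g}", f"{ch.log2_ratio:.6g}",
                    ch.direction, int(ch.excluded_by_peak_filter), int(ch.degenerate),
                )
                for ch in annotated
            ),
            ddir / "bins.tsv",
            header=(
                "chrom", "start", "end", "mean_a", "mean_b", "log2_ratio",
                "direction", "excluded_by_peak_filter", "degenerate",
            ),
        )
        produced += [ddir / "increased.bed", ddir / "decreased.bed", ddir / "bins.tsv"]
        summary["diffacc"] = {"n_increased_regions": len(inc), "n_decreased_regions": len(dec)}

    tf_peaks = None
    assignment = None
    if config.stages.get("modes"):
        config.require_inputs("modes", ["tf_peaks"] + [f"track_{t}" for t in MODE_TRACKS])
        tf_peaks = read_peaks(config.inputs["tf_peaks"], p_threshold)
        tracks = {t: read_signal(config.inputs[f"track_{t}"]) for t in MODE_TRACKS}
        matrix = extract_matrix(
            tf_peaks,
            tracks,
            window=params.get("window", 4000),
            n_bins=params.get("n_bins", 40),
        )
        assignment = cluster_modes(
            matrix, k=params.get("k", 4), seed=config.seed,
            n_init=params.get("n_init", 10),
        )
        assignment = label_clusters(
            assignment, "atac_condA", "atac_condB", "k27me3_condA",
            margin=params.get("label_margin", 1.5),
        )
        mdir = out / "modes"
        mdir.mkdir(exist_ok=True)
        write_tsv(
            (
                (
                    p.interval.chrom, p.interval.start, p.interval.end, p.name,
                    int(assignment.cluster[i]), assignment.label_of(i),
                )
                for i, p in enumerate(tf_peaks)
            ),
            mdir / "modes.tsv",
            header=("chrom", "start", "end", "name", "cluster", "label"),
        )
        cent = assignment.centroids.copy()
        cent.insert(0, "label", [assignment.labels[c] for c in cent.index])
        cent.to_csv(mdir / "centroids.tsv", sep="\t", float_format="%.6g")
        produced += [mdir / "modes.tsv", mdir / "centroids.tsv"]
        counts = {}
        for i in range(len(tf_peaks)):
            counts[assignment.label_of(i)] = counts.get(assignment.label_of(i), 0) + 1
        summary["modes"] = {"cluster_sizes": dict(sorted(counts.items()))}

    region_classes = None
    if config.stages.get("motifs"):
        config.require_inputs("motifs", ["tf_peaks", "genome_fasta"])
        if tf_peaks is None:
            tf_peaks = read_peaks(config.inputs["tf_peaks"], p_threshold)
        genome = read_fasta(config.inputs["genome_fasta"])
        pwms = (
            {name: read_pwm(p) for name, p in params["pwm_files"].items()}
            if "pwm_files" in params
            else default_pwms()
        )
        hits, region_classes = classify_peak_regions(
            tf_peaks, genome, pwms, scan_half=params.get("scan_half", 150)
        )
        odir = out / "motifs"
        odir.mkdir(exist_ok=True)
        with open(odir / "hits.bed", "w") as fh:
            for h in hits:
                fh.write(
                    f"{h.interval.chrom}\t{h.interval.start}\t{h.interval.end}\t"
                    f"{h.motif}\t{h.score:.4g}\t{h.strand}\n"
                )
        region_classes.to_csv(odir / "region_classes.tsv", sep="\t", index=False)
        produced += [odir / "hits.bed", odir / "region_classes.tsv"]
        share = region_classes["motif_class"].value_counts(normalize=True)
        summary["motifs"] = {"class_fractions": {k: round(float(v), 4) for k, v in share.items()}}

    if config.stages.get("echo"):
        config.require_inputs("echo", ["fragments", "fragment_peaks"])
        fragments = read_fragments(config.inputs["fragments"])
        fpeaks = read_peaks(config.inputs["fragment_peaks"], p_threshold)
        foci = find_all_foci(fragments, fpeaks, min_support=params.get("min_support", 1))
        edir = out / "echo"
        edir.mkdir(exist_ok=True)
        write_tsv(
            (
                (f.chrom, f.position, f.peak.name, f.n_fragments,
                 f"{f.mean_fragment_size:.4f}", f.mode)
                for f in foci
            ),
            edir / "foci.tsv",
            header=("chrom", "position", "peak", "n_fragments", "mean_size", "mode"),
        )
        produced.append(edir / "foci.tsv")
        n_direct = sum(f.mode == "direct" for f in foci)
        n_nuc = sum(f.mode == "nucleosomal" for f in foci)
        summary["echo"] = {"n_foci": len(foci), "n_direct": n_direct, "n_nucleosomal": n_nuc}

    if config.stages.get("targets"):
        config.require_inputs("targets", ["tf_peaks", "genes", "expression"])
        if tf_peaks is None:
            tf_peaks = read_peaks(config.inputs["tf_peaks"], p_threshold)
        import pandas as pd

        expr = pd.read_csv(config.inputs["expression"], sep="\t").set_index("gene_id")[
            "log2_ratio"
        ]
        mapping = associate_regions_to_genes(
            [p.interval for p in tf_peaks], genes,
            max_distance=params.get("max_distance", 100_000),
        )
        up, down = call_direct_targets(
            mapping, expr, min_abs_log2=params.get("min_abs_log2", 0.5)
        )
        tdir = out / "targets"
        tdir.mkdir(exist_ok=True)
        write_tsv(
            [(g, "up") for g in up] + [(g, "down") for g in down],
            tdir / "direct_targets.tsv",
            header=("gene_id", "direction"),
        )
        produced.append(tdir / "direct_targets.tsv")
        summary["targets"] = {"n_up": len(up), "n_down": len(down)}

    manifest = {
        "version": __version__,
        "config_hash": config_hash,
        "files": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(produced))
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
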