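"""End-to-end pipeline runs: config, stage orchestration, manifest, report.

A run is described by a :class:`RunConfig` (usually loaded from YAML):
input files by role, a parameter block, an output directory and a seed.
``run_pipeline`` executes the requested stages in dependency order, writes
every output under the output directory and records each file with a
content hash in a manifest, so that a rerun with the same config and seed
reproduces the hashes of all deterministic stages.

Stage vocabulary: ``generate`` (synthetic inputs), ``scan`` (bins +
segments + proteome summary), ``classify`` (CF calls + ROC), ``compose``
(composition + CH features), ``conserve`` (MSA statistics), ``burden``
(variant burden + Fisher), ``structmetrics`` (secondary structure per
structure file), ``ssp`` (chemical-shift propensities), ``report``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import burden as burden_mod
from . import conserve as conserve_mod
from . import seqfeat, ssp, structures, synthetic, tracks as tracks_mod
from .folding import best_operating_point, classify_idrs, roc_curve

__all__ = ["RunConfig", "ConfigError", "StageError", "run_pipeline", "write_report"]

STAGES = (
    "generate", "scan", "classify", "compose", "conserve",
    "burden", "structmetrics", "ssp", "report",
)


class ConfigError(ValueError):
    """Invalid run configuration (bad parameter or missing input)."""


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class RunConfig:
    output_dir: Path
    stages: list[str] = field(default_factory=lambda: ["scan"])
    inputs: dict = field(default_factory=dict)   # role -> path
    params: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            output_dir=Path(raw.get("output_dir", "idrfold_out")),
            stages=list(raw.get("stages", ["scan"])),
            inputs={k: Path(v) for k, v in (raw.get("inputs") or {}).items()},
            params=dict(raw.get("params") or {}),
            seed=int(raw.get("seed", 0)),
        )

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        for role, path in self.inputs.items():
            if not Path(path).exists():
                raise ConfigError(f"input {role!r}: path {path} does not exist")
        thr = self.params.get("disorder_threshold", 0.5)
        if not 0.0 <= thr <= 1.0:
            raise ConfigError(f"disorder_threshold {thr} outside [0, 1]")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_track_tsv(values: dict[str, np.ndarray], path: Path, name: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {name}: protein_id, 1-based position, value\n")
        for pid, arr in values.items():
            for i, v in enumerate(arr, start=1):
                fh.write(f"{pid}\t{i}\t{v:.4f}\n")


def _read_track_tsv(path: Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["protein_id", "pos", "value"],
                     dtype={"protein_id": str, "pos": int, "value": float})
    out = {}
    for pid, sub in df.groupby("protein_id", sort=False):
        pos = sub["pos"].to_numpy()
        if not np.array_equal(pos, np.arange(1, len(pos) + 1)):
            raise ValueError(f"{pid}: positions not contiguous from 1")
        out[pid] = sub["value"].to_numpy()
    return out


def _load_tracks(config: RunConfig) -> dict[str, tracks_mod.ResidueTrack]:
    disorder = tracks_mod.read_disorder_track(config.inputs["disorder_tracks"])
    plddt = _read_track_tsv(config.inputs["plddt_tracks"])
    labels = {}
    if "cf_labels" in config.inputs:
        labels = _read_track_tsv(config.inputs["cf_labels"])
    sequences = {}
    if "sequences" in config.inputs:
        sequences = seqfeat.read_fasta_sequences(config.inputs["sequences"])
    out = {}
    for pid in disorder:
        if pid not in plddt:
            raise ValueError(f"{pid}: disorder track without pLDDT track")
        extra = {"cf_truth": labels[pid].astype(bool)} if pid in labels else {}
        out[pid] = tracks_mod.merge_tracks(
            plddt[pid], disorder[pid], sequence=sequences.get(pid, ""),
            protein_id=pid, labels=extra,
        )
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return the manifest."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "params": config.params,
        "stages": {},
    }
    ordered = [s for s in STAGES if s in config.stages]
    for stage in ordered:
        try:
            outputs = _STAGE_FUNCS[stage](config, out_dir, manifest)
        except (ConfigError, StageError):
            raise
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in outputs}
        }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _stage_generate(config: RunConfig, out_dir: Path, manifest: dict) -> list[Path]:
    p = config.params.get("generate", {})
    spec = synthetic.SyntheticProteomeSpec(
        n_proteins=int(p.get("n_proteins", 50)),
        length_range=tuple(p.get("length_range", (300, 700))),
        frac_disordered=float(p.get("frac_disordered", 0.30)),
        frac_cf_of_disordered=float(p.get("frac_cf_of_disordered", 0.15)),
        seed=config.seed,
    )
    gen_tracks, truth = synthetic.gen_proteome_tracks(spec)
    outputs = []
    path = out_dir / "disorder.tsv"
    tracks_mod.write_disorder_track_tsv(
        {t.protein_id: t.disorder for t in gen_tracks}, path)
    outputs.append(path)
    path = out_dir / "plddt.tsv"
    _write_track_tsv({t.protein_id: t.plddt for t in gen_tracks}, path, "pLDDT")
    outputs.append(path)
    path = out_dir / "cf_labels.tsv"
    _write_track_tsv(
        {pid: arr.astype(float) for pid, arr in truth.cf.items()}, path,
        "conditional-folding truth (0/1)")
    outputs.append(path)
    path = out_dir / "sequences.fasta"
    with open(path, "w") as fh:
        for t in gen_tracks:
            fh.write(f">{t.protein_id}\n{t.sequence}\n")
    outputs.append(path)
    rates = p.get("variant_rates")
    if rates:
        variants = synthetic.gen_variant_set(truth, rates, seed=config.seed + 1)
        path = out_dir / "variants.tsv"
        burden_mod.write_variants_tsv(variants, path)
        outputs.append(path)
    # register generated files as inputs for downstream stages
    config.inputs.setdefault("disorder_tracks", out_dir / "disorder.tsv")
    config.inputs.setdefault("plddt_tracks", out_dir / "plddt.tsv")
    config.inputs.setdefault("cf_labels", out_dir / "cf_labels.tsv")
    config.inputs.setdefault("sequences", out_dir / "sequences.fasta")
    if rates:
        config.inputs.setdefault("variants", out_dir / "variants.tsv")
    return outputs


def _stage_scan(config: RunConfig, out_dir: Path, manifest: dict) -> list[Path]:
    track_map = _load_tracks(config)
    thr = config.params.get("disorder_threshold", 0.5)
    min_len = int(config.params.get("min_segment_len", 1))
    bins = tracks_mod.bin_residues(track_map.values(), thr)
    bins_path = out_dir / "bins.tsv"
    with open(bins_path, "w") as fh:
        fh.write("# residue counts per (order class x pLDDT bin)\n")
        bins.to_csv(fh, sep="\t")
    segments = []
    for t in track_map.values():
        segments.extend(tracks_mod.extract_idr_segments(t, thr, min_len))
    seg_path = out_dir / "segments.tsv"
    tracks_mod.write_segments_tsv(segments, track_map, seg_path)
    summary = tracks_mod.proteome_summary(track_map.values(), disorder_threshold=thr)
    sum_path = out_dir / "summary.json"
    tracks_mod.write_summary_json(summary, sum_path)
    return [bins_path, seg_path, sum_path]


def _stage_classify(config: RunConfig, out_dir: Path, manifest: dict) -> list[Path]:
    track_map = _load_tracks(config)
    thr = config.params.get("disorder_threshold", 0.5)
    plddt_thr = float(config.params.get("plddt_threshold", 70.0))
    min_consec = int(config.params.get("min_consecutive", 10))
    segments = []
    for t in track_map.values():
        segments.extend(tracks_mod.extract_idr_segments(t, thr))
    calls = classify_idrs(segments, track_map, plddt_thr, min_consec)
    calls_path = out_dir / "cf_calls.tsv"
    with open(calls_path, "w") as fh:
        fh.write("# conditional-folding calls; start/end 1-based inclusive\n")
        fh.write("protein_id\tstart\tend\tcf_call\n")
        for seg, is_cf in calls.items():
            fh.write(f"{seg.protein_id}\t{seg.start}\t{seg.end}\t{int(is_cf)}\n")
    outputs = [calls_path]
    # residue-level ROC when CF truth labels are available
    scores, labels = [], []
    for t in track_map.values():
        if "cf_truth" not in t.labels:
            continue
        mask = t.disordered_mask(thr)
        scores.append(t.plddt[mask])
        labels.append(t.labels["cf_truth"][mask])
    if scores:
        scores = np.concatenate(scores)
        labels = np.concatenate(labels)
        if labels.any() and not labels.all():
            roc = roc_curve(scores, labels)
            op = best_operating_point(roc)
            roc_tsv = out_dir / "roc.tsv"
            with open(roc_tsv, "w") as fh:
                fh.write("threshold\ttpr\tfpr\n")
                for k in range(len(roc.thresholds)):
                    fh.write(
                        f"{roc.thresholds[k]:.4f}\t{roc.tpr[k + 1]:.6f}\t"
                        f"{roc.fpr[k + 1]:.6f}\n"
                    )
            roc_json = out_dir / "roc.json"
            roc_json.write_text(json.dumps({
                "auc": roc.auc,
                "n_positive": roc.n_positive,
                "n_negative": roc.n_negative,
                "operating_point": {
                    "threshold": op.threshold, "tpr": op.tpr, "fpr": op.fpr,
                    "tpr_fpr_ratio": op.ratio if np.isfinite(op.ratio) else None,
                    "degenerate": op.degenerate,
                },
            }, indent=2) + "\n")
            outputs += [roc_tsv, roc_json]
    return outputs


def _stage_compose(config: RunConfig, out_dir: Path, manifest: dict) -> list[Path]:
    track_map = _load_tracks(config)
    thr = config.params.get("disorder_threshold", 0.5)
    class_seqs: dict[str, list[str]] = {"ordered": [], "idr_low": [], "idr_high": []}
    for t in track_map.values():
        if not t.sequence:
            raise ValueError(f"{t.protein_id}: compose stage needs sequences")
        seq = np.array(list(t.sequence))
        dis = t.disordered_mask(thr)
        class_seqs["ordered"].append("".join(seq[~dis]))
        class_seqs["idr_low"].append("".join(seq[dis & (t.plddt < 50)]))
        class_seqs["idr_high"].append("".join(seq[dis & (t.plddt >= 70)]))
    freqs = {
        cls: seqfeat.aa_frequencies(seqs)
        for cls, seqs in class_seqs.items() if any(seqs)
    }
    table = pd.DataFrame(freqs)
    if {"idr_low", "ordered"} <= freqs.keys():
        table["delta_order"] = seqfeat.composition_delta(
            freqs["idr_low"], freqs["ordered"])
    if {"idr_low", "idr_high"} <= freqs.keys():
        table["delta_idr_high"] = seqfeat.composition_delta(
            freqs["idr_low"], freqs["idr_high"])
    comp_path = out_dir / "composition.tsv"
    with open(comp_path, "w") as fh:
        fh.write("# amino-acid percentages per class and percent-change deltas\n")
        table.to_csv(fh, sep="\t")
    ch = {
        cls: vars(seqfeat.ch_features("".join(seqs)))
        for cls, seqs in class_seqs.items() if any(seqs)
    }
    ch_path = out_dir / "ch_features.json"
    ch_path.write_text(json.dumps(ch, indent=2, sort_keys=True) + "\n")
    return [comp_path, ch_path]


def _stage_conserve(config: RunConfig, out_dir: Path, manifest: dict) -> list[Path]:
    msa = conserve_mod.read_msa(config.inputs["msa"])
    cons = conserve_mod.positional_conservation(msa)
    depth = conserve_mod.alignment_depth(msa)
    path = out_dir / "conservation.json"
    path.write_text(json.dumps({
        "mean_positional_conservation": cons.mean,
        "n_columns": cons.n_columns,
        "n_excluded_columns": cons.n_excluded,
        "mean_alignment_depth": depth.mean,
        "n_rows": msa.n_rows,
    }, indent=2) + "\n")
    return [path]


def _stage_burden(config: RunConfig, out_dir: Path, manifest: dict) -> list[Path]:
    track_map = _load_tracks(config)
    thr = config.params.get("disorder_threshold", 0.5)
    variants = burden_mod.read_variants_tsv(config.inputs["variants"])
    counts, excluded = burden_mod.map_variants_to_classes(variants, track_map, thr)
    totals = burden_mod.residue_totals(track_map, thr)
    table = burden_mod.burden_table(counts, totals)
    path = out_dir / "burden.tsv"
    with open(path, "w") as fh:
        fh.write("# per-residue mutational burden per region class\n")
        table.to_csv(fh, sep="\t", index=False)
    tests = {}
    for label in table["label"].unique():
        sub = table[table["label"] == label].set_index("region_class")
        low = "idr_very_low"
        highs = [c for c in ("idr_confident", "idr_very_confident") if c in sub.index]
        if low in sub.index and highs:
            n_mut_high = int(sub.loc[highs, "n_mutations"].sum())
            n_res_high = int(sub.loc[highs, "n_residues"].sum())
            fisher = burden_mod.fisher_exact(
                int(sub.loc[low, "n_mutations"]),
                int(sub.loc[low, "n_residues"] - sub.loc[low, "n_mutations"]),
                n_mut_high, n_res_high - n_mut_high,
            )
            burden_low = sub.loc[low, "burden"]
            burden_high = n_mut_high / n_res_high if n_res_high else float("nan")
            tests[str(label)] = {
                "p": fisher.p,
                "odds_ratio": fisher.odds_ratio,
                "fold_ratio_low_over_high": (
                    burden_low / burden_high if burden_high else None),
            }
    tests_path = out_dir / "burden_tests.json"
    tests_path.write_text(json.dumps(tests, indent=2, sort_keys=True) + "\n")
    return [path, tests_path]


def _stage_structmetrics(config: RunConfig, out_dir: Path, manifest: dict) -> list[Path]:
    struct_dir = Path(config.inputs["structures"])
    files = sorted(struct_dir.glob("*.pdb")) + sorted(struct_dir.glob("*.cif"))
    if not files:
        raise ValueError(f"no structure files in {struct_dir}")
    rows = []
    for f in files:
        model = structures.read_structure(f)
        ss = structures.assign_ss3(model)
        plddt = structures.plddt_from_bfactor(model)
        rows.append((f.name, len(ss),
                     100.0 * ss.count("H") / len(ss),
                     100.0 * ss.count("E") / len(ss),
                     100.0 * ss.count("C") / len(ss),
                     float(np.mean(plddt))))
    path = out_dir / "structmetrics.tsv"
    with open(path, "w") as fh:
        fh.write("file\tn_residues\tpct_H\tpct_E\tpct_C\tmean_plddt\n")
        for r in rows:
            fh.write("\t".join(str(x) if isinstance(x, (str, int)) else f"{x:.2f}"
                               for x in r) + "\n")
    return [path]


def _stage_ssp(config: RunConfig, out_dir: Path, manifest: dict) -> list[Path]:
    table = ssp.read_shift_table(config.inputs["shifts"])
    deltas = ssp.secondary_shifts(table)
    window = int(config.params.get("ssp_window", 5))
    track = ssp.ssp_track(deltas, window=window)
    path = out_dir / "ssp.tsv"
    with open(path, "w") as fh:
        fh.write("# SSP per residue; 'nan' = undefined (too few observations)\n")
        fh.write("resi\taa\tssp\n")
        for resi, aa, val in zip(deltas["resi"], deltas["aa"], track):
            fh.write(f"{resi}\t{aa}\t{'nan' if np.isnan(val) else f'{val:.4f}'}\n")
    return [path]


def _stage_report(config: RunConfig, out_dir: Path, manifest: dict) -> list[Path]:
    return write_report(manifest, out_dir)


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "scan": _stage_scan,
    "classify": _stage_classify,
    "compose": _stage_compose,
    "conserve": _stage_conserve,
    "burden": _stage_burden,
    "structmetrics": _stage_structmetrics,
    "ssp": _stage_ssp,
    "report": _stage_report,
}


def write_report(manifest: dict, out_dir: str | Path) -> list[Path]:
    """Write a human-readable Markdown + JSON summary of a run."""
    out_dir = Path(out_dir)
    stages = manifest.get("stages", {})
    lines = ["# idrfold run report", ""]
    if not stages:
        lines.append("no stages run")
    for name, info in stages.items():
        lines.append(f"## {name}")
        for fname in sorted(info.get("outputs", {})):
            lines.append(f"- `{fname}`")
        lines.append("")
    summary: dict = {"stages": sorted(stages)}
    for fname, key in (("summary.json", "proteome"), ("roc.json", "roc"),
                       ("burden_tests.json", "burden"),
                       ("conservation.json", "conservation")):
        path = out_dir / fname
        if path.exists():
            summary[key] = json.loads(path.read_text())
            lines.append(f"## {key}")
            for k, v in summary[key].items():
                lines.append(f"- {k}: {v}")
            lines.append("")
    md = out_dir / "report.md"
    md.write_text("\n".join(lines) + "\n")
    js = out_dir / "report.json"
    js.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return [md, js]
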