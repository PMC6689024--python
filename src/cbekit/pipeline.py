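"""End-to-end driver: simulate -> quantify -> windows -> preference -> specificity.

A single :class:`RunConfig` seed drives every stage; per-stage seeds are
derived deterministically from it, so re-running an identical config
reproduces byte-identical outputs.  The bundled demo mode simulates the
built-in editor archetypes over a designed sgRNA panel, multiplexes them
with per-editor barcodes, and runs the full analysis; pointing the config
at site/FASTA/FASTQ files analyzes real amplicon data instead.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from cbekit import io as cio
from cbekit.coords import TargetSite, load_sites
from cbekit.preference import analyze_preference
from cbekit.quantify import ConversionTable, quantify_reads
from cbekit.simulate import (
    EditorProfile,
    ReadBatch,
    make_profile_library,
    make_sgrna_panel,
    make_synthetic_site,
    simulate_reads,
)
from cbekit.specificity import specificity_panel
from cbekit.windows import ClassifierConfig, analyze_editor

__all__ = ["RunConfig", "run_pipeline"]

_BARCODES = ["ACGTCA", "TGCAGT", "GATCGA", "CTAGTC", "AGCTAG", "TCGATC", "GTACGT", "CATGCA"]


@dataclass
class RunConfig:
    """All tunables of a pipeline run (thresholds, sizes, seed, inputs)."""

    seed: int = 7
    n_reads: int = 5000
    n_sgrnas: int = 6
    q_min: int = 15
    scope_threshold: float = 0.40
    cew_threshold: float = 0.6
    pref_min_norm: float = 0.8
    min_activity: float = 0.05
    min_depth: int = 1
    tie_tol: float = 0.05
    seed_len: int = 20
    max_mm: float = 0.2
    broad_span: int = 12
    broad_lo: int = 2
    broad_hi: int = 9
    backward_min_start: int = 7
    off_activity: float = 0.2
    # optional real-data inputs; demo simulation runs when these are unset
    sites_tsv: Optional[str] = None
    fasta: Optional[str] = None
    fastq: Optional[str] = None
    barcodes_tsv: Optional[str] = None

    def __post_init__(self) -> None:
        for name in (
            "scope_threshold",
            "cew_threshold",
            "pref_min_norm",
            "min_activity",
            "max_mm",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.q_min < 0:
            raise ValueError("q_min must be >= 0")

    @property
    def classifier(self) -> ClassifierConfig:
        return ClassifierConfig(self.broad_span, self.broad_lo, self.broad_hi, self.backward_min_start)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _stage_seed(base: int, *indices: int) -> int:
    """Deterministic per-stage seed derived from the run seed."""
    h = base
    for i in indices:
        h = (h * 1000003 + i + 1) % 2**31
    return h


def run_pipeline(config: RunConfig, outdir) -> Dict[str, object]:
    """Execute all stages, write TSV outputs plus a run manifest, return the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    try:
        from importlib.metadata import version

        manifest["cbekit_version"] = version("cbekit")
    except Exception:
        manifest["cbekit_version"] = "unknown"
    manifest["numpy_version"] = np.__version__

    if config.fastq:
        tables_by_editor = _quantify_real(config, out, manifest)
        panel = None
    else:
        tables_by_editor, panel = _simulate_and_quantify(config, out, manifest)

    # window analysis + classification per editor
    window_rows, scope_rows = [], []
    window_results = {}
    for editor_id, per_sg in tables_by_editor.items():
        raw = {
            sg: tbl.c_to_t_frequencies(min_depth=config.min_depth)
            for sg, tbl in per_sg.items()
        }
        res = analyze_editor(
            editor_id,
            raw,
            scope_threshold=config.scope_threshold,
            cew_threshold=config.cew_threshold,
            classifier=config.classifier,
        )
        window_results[editor_id] = res
        for cp in sorted(res.mean_norm):
            window_rows.append(
                {"editor_id": editor_id, "cp": cp, "mean_norm": f"{res.mean_norm[cp]:.6g}",
                 "in_cew": int(cp in res.cew), "class_label": res.class_label}
            )
        for sg, cps in sorted(res.scope.items()):
            scope_rows.extend(
                {"editor_id": editor_id, "sgrna_id": sg, "cp": cp} for cp in sorted(cps)
            )
    import pandas as pd

    pd.DataFrame(window_rows, columns=["editor_id", "cp", "mean_norm", "in_cew", "class_label"]).to_csv(
        out / "windows.tsv", sep="\t", index=False
    )
    pd.DataFrame(scope_rows, columns=["editor_id", "sgrna_id", "cp"]).to_csv(
        out / "scope.tsv", sep="\t", index=False
    )
    manifest["stages"]["windows"] = {
        e: {"class": r.class_label, "cew": sorted(r.cew)} for e, r in window_results.items()
    }

    # substrate preference (needs the sites themselves for context lookup)
    if panel is not None:
        pref_results = []
        site_by_id = {s.site_id: s for s in panel}
        for editor_id, per_sg in tables_by_editor.items():
            wr = window_results[editor_id]
            pairs = [(site_by_id[sg], wr.normalized[sg]) for sg in wr.normalized]
            res = analyze_preference(
                editor_id, pairs, min_norm=config.pref_min_norm, tie_tol=config.tie_tol
            )
            pref_results.extend(res.values())
        cio.write_preference_results(pref_results, out / "preference.tsv")
        manifest["stages"]["preference"] = {
            f"{r.editor_id}:{r.direction}": r.ordering for r in pref_results
        }

        # specificity: on-target = first panel site; one simulated off-target
        spec_results = []
        for e_i, (editor_id, per_sg) in enumerate(tables_by_editor.items()):
            profile = next(p for p in make_profile_library() if p.editor_id == editor_id)
            on_id = panel[0].site_id
            off_site = make_synthetic_site(
                f"off_{editor_id}",
                _stage_seed(config.seed, 900, e_i),
                {4: "T", 6: "A", 8: "G", 10: "T", 12: "A"},
            )
            off_profile = dataclasses.replace(
                profile,
                p_edit={cp: p * config.off_activity for cp, p in profile.p_edit.items()},
            )
            batch, _ = simulate_reads(
                off_site, off_profile, config.n_reads, _stage_seed(config.seed, 901, e_i)
            )
            off_tbl = quantify_reads(
                batch, off_site, q_min=config.q_min,
                seed_len=config.seed_len, max_mm=config.max_mm,
            ).tables["default"]
            per_pair, worst = specificity_panel(
                editor_id,
                {on_id: per_sg[on_id]},
                {off_site.site_id: off_tbl},
                [(on_id, off_site.site_id)],
                min_activity=config.min_activity,
                min_depth=config.min_depth,
            )
            spec_results.extend(per_pair)
        cio.write_specificity_results(spec_results, out / "specificity.tsv")
        manifest["stages"]["specificity"] = {
            f"{r.editor_id}:{r.off_site_id}": r.label for r in spec_results
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _simulate_and_quantify(
    config: RunConfig, out: Path, manifest: Dict[str, object]
) -> Tuple[Dict[str, Dict[str, ConversionTable]], List[TargetSite]]:
    """Demo mode: simulate the archetype editors over a designed panel."""
    profiles = make_profile_library()
    panel = make_sgrna_panel(
        config.n_sgrnas, _stage_seed(config.seed, 1), per_position=min(2, config.n_sgrnas)
    )
    barcode_map = {_BARCODES[i]: p.editor_id for i, p in enumerate(profiles)}
    reads_dir = out / "reads"
    reads_dir.mkdir(exist_ok=True)

    tables: Dict[str, Dict[str, ConversionTable]] = {p.editor_id: {} for p in profiles}
    truths = []
    counts = {"total_reads": 0, "assigned": 0, "unassigned": 0, "unplaced": 0,
              "ambiguous": 0, "rejected_mismatch": 0, "discarded_short": 0}
    for s_i, site in enumerate(panel):
        batches = []
        for e_i, profile in enumerate(profiles):
            batch, truth = simulate_reads(
                site, profile, config.n_reads, _stage_seed(config.seed, 2, s_i, e_i),
                barcode=_BARCODES[e_i],
            )
            batches.append(batch)
            truths.append(truth)
        pooled = ReadBatch(
            np.concatenate([b.seq for b in batches]),
            np.concatenate([b.qual for b in batches]),
            id_prefix=site.site_id,
        )
        with open(reads_dir / f"{site.site_id}.fastq", "w") as fh:
            pooled.to_fastq(fh)
        result = quantify_reads(
            pooled, site, barcode_map=barcode_map, q_min=config.q_min,
            seed_len=config.seed_len, max_mm=config.max_mm,
        )
        counts["total_reads"] += len(pooled)
        counts["assigned"] += sum(result.assigned.values())
        counts["unassigned"] += result.unassigned
        counts["unplaced"] += result.unplaced
        counts["ambiguous"] += result.ambiguous
        counts["rejected_mismatch"] += result.rejected_mismatch
        counts["discarded_short"] += result.discarded_short
        for editor_id, tbl in result.tables.items():
            tables[editor_id][site.site_id] = tbl

    cio.write_truth(truths, out / "truth.tsv")
    import pandas as pd

    frames = [
        cio.conversion_table_to_frame(tbl, config.min_depth)
        for per_sg in tables.values()
        for tbl in per_sg.values()
    ]
    pd.concat(frames, ignore_index=True).to_csv(out / "tables.tsv", sep="\t", index=False)
    manifest["stages"]["quantify"] = counts
    return tables, panel


def _quantify_real(
    config: RunConfig, out: Path, manifest: Dict[str, object]
) -> Dict[str, Dict[str, ConversionTable]]:
    """Real-data mode: quantify an existing FASTQ against annotated sites."""
    for name in ("sites_tsv", "fasta", "fastq"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"pipeline input {name} missing: {path}")
    sites = load_sites(config.sites_tsv, config.fasta)
    barcode_map = cio.load_barcodes(config.barcodes_tsv) if config.barcodes_tsv else {}
    tables: Dict[str, Dict[str, ConversionTable]] = {}
    counts: Dict[str, object] = {}
    import pandas as pd

    frames = []
    for site in sites:
        result = quantify_reads(
            cio.read_fastq(config.fastq), site, barcode_map=barcode_map,
            q_min=config.q_min, seed_len=config.seed_len, max_mm=config.max_mm,
        )
        counts[site.site_id] = {
            "assigned": result.assigned, "unassigned": result.unassigned,
            "unplaced": result.unplaced, "ambiguous": result.ambiguous,
            "rejected_mismatch": result.rejected_mismatch,
        }
        for sample, tbl in result.tables.items():
            tables.setdefault(sample, {})[site.site_id] = tbl
            frames.append(cio.conversion_table_to_frame(tbl, config.min_depth))
    pd.concat(frames, ignore_index=True).to_csv(out / "tables.tsv", sep="\t", index=False)
    manifest["stages"]["quantify"] = counts
    return tables
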