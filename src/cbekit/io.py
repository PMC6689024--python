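"""File formats: FASTQ/FASTA readers, TSV tables, profile configs.

All tabular output is tab-separated UTF-8 with a mandatory header row and
"NA" for missing values.  FASTQ is plain 4-line Phred+33.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from cbekit.quantify import ConversionTable, QuantifyResult
from cbekit.simulate import EditorProfile, FastqRead, ReadBatch, SimTruth
from cbekit.specificity import SpecificityResult
from cbekit.preference import PreferenceResult
from cbekit.windows import WindowResult

__all__ = [
    "read_fastq",
    "write_fastq",
    "write_truth",
    "conversion_table_to_frame",
    "write_conversion_table",
    "read_conversion_table",
    "write_window_result",
    "write_preference_results",
    "write_specificity_results",
    "load_barcodes",
    "load_pairs",
    "profile_to_yaml",
    "profile_from_yaml",
]

NA = "NA"


def read_fastq(path: Union[str, Path]) -> Iterator[FastqRead]:
    """Stream FASTQ records; malformed records raise with the record index."""
    with open(path) as fh:
        try:
            for i, (title, seq, qual) in enumerate(FastqGeneralIterator(fh)):
                if len(seq) != len(qual):
                    raise ValueError(
                        f"{path}: record {i} ({title}): sequence/quality length mismatch"
                    )
                yield FastqRead(title.split()[0], seq.upper(), qual)
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc


def write_fastq(reads: Union[ReadBatch, Sequence[FastqRead]], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        if isinstance(reads, ReadBatch):
            reads.to_fastq(fh)
        else:
            for r in reads:
                fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def write_truth(truths: Sequence[SimTruth], path: Union[str, Path]) -> None:
    rows = [
        {"site_id": t.site_id, "cp": cp, "expected_freq": f, "n_reads": t.n_reads, "seed": t.seed}
        for t in truths
        for cp, f in sorted(t.expected.items())
    ]
    pd.DataFrame(rows, columns=["site_id", "cp", "expected_freq", "n_reads", "seed"]).to_csv(
        path, sep="\t", index=False
    )


def conversion_table_to_frame(table: ConversionTable, min_depth: int = 1) -> pd.DataFrame:
    depth = table.depth
    rows = []
    for i, cp in enumerate(table.cps):
        d = int(depth[i])
        if table.ref_bases[i] == "C" and d >= max(min_depth, 1):
            freq = f"{table.counts[i, 3] / d:.6g}"
        else:
            freq = NA
        rows.append(
            {
                "site_id": table.site_id,
                "sample_id": table.sample_id,
                "cp": cp,
                "ref_base": table.ref_bases[i],
                "A": int(table.counts[i, 0]),
                "C": int(table.counts[i, 1]),
                "G": int(table.counts[i, 2]),
                "T": int(table.counts[i, 3]),
                "depth": d,
                "freq_C_to_T": freq,
            }
        )
    return pd.DataFrame(rows)


def write_conversion_table(
    table: ConversionTable, path: Union[str, Path], min_depth: int = 1
) -> None:
    conversion_table_to_frame(table, min_depth).to_csv(path, sep="\t", index=False)


def read_conversion_table(path: Union[str, Path]) -> List[ConversionTable]:
    """Read one or more conversion tables (grouped by site_id x sample_id)."""
    import numpy as np

    df = pd.read_csv(path, sep="\t", dtype={"ref_base": str})
    tables = []
    for (site_id, sample_id), grp in df.groupby(["site_id", "sample_id"], sort=False):
        counts = grp[["A", "C", "G", "T"]].to_numpy(dtype=np.int64)
        tables.append(
            ConversionTable(
                str(site_id), str(sample_id), [int(c) for c in grp["cp"]],
                list(grp["ref_base"]), counts,
            )
        )
    return tables


def write_window_result(result: WindowResult, path: Union[str, Path]) -> None:
    rows = [
        {
            "editor_id": result.editor_id,
            "cp": cp,
            "mean_norm": f"{result.mean_norm[cp]:.6g}",
            "in_cew": int(cp in result.cew),
            "class_label": result.class_label,
        }
        for cp in sorted(result.mean_norm)
    ]
    pd.DataFrame(rows, columns=["editor_id", "cp", "mean_norm", "in_cew", "class_label"]).to_csv(
        path, sep="\t", index=False
    )


def write_scope(result: WindowResult, path: Union[str, Path]) -> None:
    rows = [
        {"editor_id": result.editor_id, "sgrna_id": sg, "cp": cp}
        for sg, cps in sorted(result.scope.items())
        for cp in sorted(cps)
    ]
    pd.DataFrame(rows, columns=["editor_id", "sgrna_id", "cp"]).to_csv(path, sep="\t", index=False)


def write_preference_results(
    results: Sequence[PreferenceResult], path: Union[str, Path]
) -> None:
    import numpy as np

    rows = []
    for r in results:
        for ctx, vals in r.groups.items():
            rows.append(
                {
                    "editor_id": r.editor_id,
                    "direction": r.direction,
                    "context": ctx,
                    "n": len(vals),
                    "mean": f"{np.mean(vals):.6g}" if vals else NA,
                    "F": f"{r.F:.6g}" if r.F is not None else NA,
                    "p": f"{r.p:.6g}" if r.p is not None else NA,
                    "ordering": r.ordering,
                }
            )
    pd.DataFrame(
        rows, columns=["editor_id", "direction", "context", "n", "mean", "F", "p", "ordering"]
    ).to_csv(path, sep="\t", index=False)


def write_specificity_results(
    results: Sequence[SpecificityResult], path: Union[str, Path]
) -> None:
    rows = [
        {
            "editor_id": r.editor_id,
            "on_site": r.on_site_id,
            "off_site": r.off_site_id,
            "onCh": f"{r.on_ch:.6g}" if r.on_ch is not None else NA,
            "offCh": f"{r.off_ch:.6g}" if r.off_ch is not None else NA,
            "specificity": f"{r.value:.6g}" if r.value is not None else NA,
            "label": r.label,
        }
        for r in results
    ]
    pd.DataFrame(
        rows, columns=["editor_id", "on_site", "off_site", "onCh", "offCh", "specificity", "label"]
    ).to_csv(path, sep="\t", index=False)


def load_barcodes(path: Union[str, Path]) -> Dict[str, str]:
    """Barcode TSV (sample_id, barcode) -> {barcode: sample_id}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "barcode"} <= set(df.columns):
        raise ValueError(f"{path}: barcode table needs columns sample_id, barcode")
    if df["barcode"].duplicated().any():
        raise ValueError(f"{path}: duplicate barcodes")
    return dict(zip(df["barcode"].str.upper(), df["sample_id"]))


def load_pairs(path: Union[str, Path]) -> List[Tuple[str, str]]:
    """On/off pairing TSV (on_site_id, off_site_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"on_site_id", "off_site_id"} <= set(df.columns):
        raise ValueError(f"{path}: pairing table needs columns on_site_id, off_site_id")
    return list(zip(df["on_site_id"], df["off_site_id"]))


def profile_to_yaml(profile: EditorProfile, path: Union[str, Path]) -> None:
    data = {
        "editor_id": profile.editor_id,
        "p_edit": {int(k): float(v) for k, v in profile.p_edit.items()},
        "context_mult": {k: float(v) for k, v in profile.context_mult.items()},
        "downstream_mult": {k: float(v) for k, v in profile.downstream_mult.items()},
        "seq_error": float(profile.seq_error),
        "base_quality": int(profile.base_quality),
        "low_q_tail_len": int(profile.low_q_tail_len),
        "low_q_score": int(profile.low_q_score),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def profile_from_yaml(path: Union[str, Path]) -> EditorProfile:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    data["p_edit"] = {int(k): float(v) for k, v in data["p_edit"].items()}
    return EditorProfile(**data)
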