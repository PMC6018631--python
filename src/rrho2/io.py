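"""Delimited-text I/O: gene lists, score matrices, truth tables, manifests.

Gene lists are TSV/CSV with a header and either (gene, dde) or
(gene, pvalue, direction) columns; direction may be coded -1/+1 or as a
signed effect size. Maps serialize as a tab-separated matrix with cutoff
indices as headers, preceded by a ``# key=value`` metadata block. Every
pipeline output directory receives a manifest recording the command,
parameters, input digests, seed and version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .maps import OverlapMap
from .ranking import GeneScore, compute_dde, sanitize_pvalues

log = logging.getLogger(__name__)

__all__ = [
    "read_gene_list",
    "write_gene_list",
    "write_map",
    "read_map",
    "write_manifest",
]


class InputFormatError(ValueError):
    """A delimited input file violates the column/value contract."""


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise InputFormatError(f"{path}: file is empty")
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_gene_list(path) -> list[GeneScore]:
    """Load a gene list; accepts (gene, dde) or (gene, pvalue, direction).

    When both dde and (pvalue, direction) are present, dde wins and any
    inconsistency is logged. Malformed cells are reported with their row
    number and column name.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"{path}: no such file")
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={0: str}, float_precision="round_trip")
    df.columns = [c.strip().lower() for c in df.columns]
    if df.empty:
        raise InputFormatError(f"{path}: no data rows")
    if "gene" not in df.columns:
        raise InputFormatError(f"{path}: missing required column 'gene'")

    has_dde = "dde" in df.columns
    has_pv = "pvalue" in df.columns and "direction" in df.columns
    if not has_dde and not has_pv:
        raise InputFormatError(
            f"{path}: need either a 'dde' column or 'pvalue' + 'direction' columns"
        )

    def numeric(col: str) -> np.ndarray:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0]) + 2  # header is line 1
            raise InputFormatError(f"{path}: non-numeric value in column {col!r}, line {row}")
        return vals.to_numpy(dtype=float)

    genes = df["gene"].astype(str)
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise InputFormatError(f"{path}: duplicate gene id {dup!r}")

    if has_dde:
        dde = numeric("dde")
        if has_pv:
            pv = sanitize_pvalues(numeric("pvalue"))
            direc = np.sign(numeric("direction")).astype(int)
            expect = -np.log10(pv) * direc
            if not np.allclose(dde, expect, rtol=1e-6, atol=1e-8):
                log.warning("%s: dde column disagrees with pvalue*direction; using dde", path)
            return [
                GeneScore(g, float(d), float(p), int(s) if s != 0 else None)
                for g, d, p, s in zip(genes, dde, pv, direc)
            ]
        return [GeneScore(g, float(d)) for g, d in zip(genes, dde)]

    pv = sanitize_pvalues(numeric("pvalue"))
    direc = np.sign(numeric("direction")).astype(int)
    if (direc == 0).any():
        row = int(np.flatnonzero(direc == 0)[0]) + 2
        raise InputFormatError(f"{path}: zero direction/effect at line {row}")
    return [
        GeneScore(g, compute_dde(float(p), int(s)), float(p), int(s))
        for g, p, s in zip(genes, pv, direc)
    ]


def write_gene_list(scores: Sequence[GeneScore], path) -> None:
    """Write gene scores as TSV (full float precision, round-trip safe)."""
    rows = {"gene": [g.gene_id for g in scores], "dde": [g.dde for g in scores]}
    if all(g.p_two_sided is not None for g in scores):
        rows["pvalue"] = [g.p_two_sided for g in scores]
        rows["direction"] = [g.direction if g.direction is not None else 0 for g in scores]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_map(overlap_map: OverlapMap, path) -> None:
    """Serialize a map: '# key=value' metadata block, then the score matrix.

    Rows are study-2 cutoffs, columns study-1 cutoffs; the counts matrix is
    written next to it as <stem>.counts.tsv.
    """
    path = Path(path)
    meta = {
        "method": overlap_map.method,
        "log_base": overlap_map.log_base,
        "step_size": overlap_map.step_size,
        "boundary_x": overlap_map.boundary_x,
        "boundary_y": overlap_map.boundary_y,
        "n_genes": overlap_map.n_genes,
        "scale_max": "" if overlap_map.scale_max is None else overlap_map.scale_max,
    }
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        frame = pd.DataFrame(
            overlap_map.scores,
            index=overlap_map.cutoffs_y,
            columns=overlap_map.cutoffs_x,
        )
        frame.to_csv(fh, sep="\t", float_format="%.17g", index_label="cutoff")
    counts = pd.DataFrame(
        overlap_map.counts, index=overlap_map.cutoffs_y, columns=overlap_map.cutoffs_x
    )
    counts.to_csv(path.with_suffix(".counts.tsv"), sep="\t", index_label="cutoff")


def read_map(path) -> OverlapMap:
    """Load a map serialized by :func:`write_map` (counts side-car optional)."""
    path = Path(path)
    meta: dict[str, str] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val
            skip += 1
    frame = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0, float_precision="round_trip")
    counts_path = path.with_suffix(".counts.tsv")
    if counts_path.exists():
        counts = pd.read_csv(counts_path, sep="\t", index_col=0).to_numpy(dtype=np.int64)
    else:
        counts = np.zeros(frame.shape, dtype=np.int64)
    return OverlapMap(
        scores=frame.to_numpy(dtype=float),
        counts=counts,
        method=meta["method"],
        log_base=meta["log_base"],
        boundary_x=int(meta["boundary_x"]),
        boundary_y=int(meta["boundary_y"]),
        step_size=int(meta["step_size"]),
        cutoffs_x=frame.columns.to_numpy(dtype=np.int64),
        cutoffs_y=frame.index.to_numpy(dtype=np.int64),
        n_genes=int(meta["n_genes"]),
        scale_max=float(meta["scale_max"]) if meta.get("scale_max") else None,
    )


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir,
    command: str,
    params: dict,
    inputs: Sequence = (),
    seed: Optional[int] = None,
) -> Path:
    """Record the run: command, parameters, input digests, seed, version."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "params": {k: (str(v) if isinstance(v, Path) else v) for k, v in params.items()},
        "inputs": {str(p): _digest(Path(p)) for p in inputs},
        "seed": seed,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
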