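"""Report rendering: publication-style tables from pipeline outputs.

Renders the candidate-model table (AICc ranking with weights), the
brood-patch breeder table, the biometric summary and the nest-outcome
summary as TSV/JSON files, plus a run manifest (inputs, seed, package
version, timestamp).  Sections whose inputs are missing are skipped with
a logged warning rather than failing the run.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

logger = logging.getLogger("petrelpop")

__all__ = [
    "render_model_table",
    "render_breeder_table",
    "render_nest_summary",
    "run_report",
]


def render_model_table(model_set) -> pd.DataFrame:
    """AICc-ranked model table with deltas, weights and parameter counts."""
    df = model_set.table()
    df = df.rename(
        columns={
            "model": "Model design",
            "AICc": "AICc",
            "deltaAICc": "Delta AICc",
            "weight": "AICc weight",
            "K": "N parameters",
        }
    )
    df.insert(0, "Model number", range(1, len(df) + 1))
    return df


def render_breeder_table(table, modes=("min", "probable", "max")) -> pd.DataFrame:
    """Year x mode breeder counts with percentages (brood-patch procedure)."""
    from .breeders import breeder_counts

    import warnings

    out = None
    for mode in modes:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df = breeder_counts(table, mode=mode)
        col = df.apply(
            lambda r: f"{int(r['count'])} ({r['percent']:.1f}%)", axis=1
        ).rename(mode)
        out = col.to_frame() if out is None else out.join(col, how="outer")
    return out


def render_nest_summary(summary: pd.DataFrame) -> pd.DataFrame:
    out = summary.copy()
    out["success"] = out["success_pct"].map(
        lambda v: f"{int(v)}%" if pd.notna(v) else "-"
    )
    return out.drop(columns=["success_pct"])


def run_report(
    out_dir,
    model_set=None,
    brood_patch_table=None,
    biometric_summary: pd.DataFrame | None = None,
    nest_summary: pd.DataFrame | None = None,
    seed: int | None = None,
    inputs: dict | None = None,
    force: bool = False,
) -> list:
    """Write all available report sections plus a run manifest.

    Returns the list of files written.  Refuses to overwrite an existing
    report directory content unless ``force`` is set.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    def emit(name, df: pd.DataFrame):
        path = out_dir / name
        if path.exists() and not force:
            raise FileExistsError(f"{path} exists; pass force=True to overwrite")
        df.to_csv(path, sep="\t")
        written.append(path)

    if model_set is not None:
        emit("model_table.tsv", render_model_table(model_set).set_index("Model number"))
        avg = {
            "averaged_N": model_set.averaged_N,
            "unconditional_se": model_set.unconditional_se,
            "ci_95": list(model_set.ci),
            "model_variation_pct": model_set.model_variation_pct,
        }
        path = out_dir / "model_average.json"
        path.write_text(json.dumps(avg, indent=2))
        written.append(path)
    else:
        logger.warning("report: model set missing; section skipped")

    if brood_patch_table is not None:
        emit("breeders.tsv", render_breeder_table(brood_patch_table))
    else:
        logger.warning("report: brood-patch table missing; section skipped")

    if biometric_summary is not None:
        emit("biometrics.tsv", biometric_summary)
    else:
        logger.warning("report: biometric summary missing; section skipped")

    if nest_summary is not None:
        emit("nests.tsv", render_nest_summary(nest_summary))
    else:
        logger.warning("report: nest summary missing; section skipped")

    manifest = {
        "package": "petrelpop",
        "version": __version__,
        "seed": seed,
        "inputs": inputs or {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": [p.name for p in written],
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    written.append(mpath)
    return written
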