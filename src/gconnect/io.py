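"""Plain-text IO for connectivity cohorts.

A cohort on disk is a manifest CSV with columns ``subject_id, group, path``
plus one dense whitespace-delimited N x N matrix text file per subject;
parcellations are two-column TSVs (``node_index<TAB>module_label``).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .connectome import ConnectivityMatrix, ParcellationScheme

__all__ = ["load_cohort", "save_cohort"]


def save_cohort(subjects: list[ConnectivityMatrix], directory) -> Path:
    """Write matrices and a manifest CSV; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        fname = f"{s.subject_id}.txt"
        s.to_text(directory / fname)
        rows.append({"subject_id": s.subject_id, "group": s.group, "path": fname})
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest_path) -> list[ConnectivityMatrix]:
    """Load a cohort from a manifest CSV (paths relative to the manifest)."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = {"subject_id", "group", "path"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    base = manifest_path.parent
    return [
        ConnectivityMatrix.from_text(
            base / row["path"], subject_id=str(row["subject_id"]), group=int(row["group"])
        )
        for _, row in df.iterrows()
    ]


def load_parcellation(path) -> ParcellationScheme:
    return ParcellationScheme.from_tsv(path)
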