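"""TSV / BIOM-JSON input-output and dataset (de)serialization.

Count tables are TSV with samples as rows: first column ``sample_id``,
remaining columns one per OTU with the OTU id in the header.  A simulated
dataset round-trips through a directory of counts.tsv, covariate.tsv,
library_sizes.tsv, truth.tsv and a config snapshot.  BIOM export/import uses
the BIOM 1.0 JSON dialect.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simgen import SimConfig, SimulatedDataset, SpikeTruth

__all__ = [
    "write_count_table",
    "read_count_table",
    "read_covariate_template",
    "write_results",
    "read_results",
    "save_dataset",
    "load_dataset",
    "write_biom_json",
    "read_biom_json",
]


def write_count_table(path, y, otu_ids=None, sample_ids=None) -> None:
    y = np.asarray(y)
    n, J = y.shape
    otu_ids = [f"OTU{j + 1}" for j in range(J)] if otu_ids is None else list(otu_ids)
    sample_ids = [f"S{i + 1}" for i in range(n)] if sample_ids is None else list(sample_ids)
    df = pd.DataFrame(y, columns=otu_ids)
    df.insert(0, "sample_id", sample_ids)
    df.to_csv(path, sep="\t", index=False)


def read_count_table(path):
    """Read a samples x OTUs TSV; returns (counts, otu_ids, sample_ids)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "sample_id":
        raise ValueError(
            f"{path}: first column must be 'sample_id', got {df.columns[0]!r}"
        )
    sample_ids = df["sample_id"].astype(str).tolist()
    body = df.drop(columns="sample_id")
    arr = body.to_numpy()
    bad = np.argwhere(~np.isfinite(arr.astype(float)) | (arr.astype(float) < 0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: negative or non-finite count at sample {sample_ids[i]!r}, "
            f"OTU {body.columns[j]!r}"
        )
    if not np.allclose(arr.astype(float), np.rint(arr.astype(float))):
        frac = np.argwhere(arr.astype(float) != np.rint(arr.astype(float)))
        i, j = frac[0]
        raise ValueError(
            f"{path}: non-integer count at sample {sample_ids[i]!r}, "
            f"OTU {body.columns[j]!r}"
        )
    return arr.astype(np.int64), body.columns.to_numpy(str), np.asarray(sample_ids)


def read_covariate_template(path) -> pd.DataFrame:
    """Read a covariate template (standardized numeric columns, TSV)."""
    df = pd.read_csv(path, sep="\t")
    return df.apply(pd.to_numeric, errors="raise")


def write_results(path, results: pd.DataFrame) -> None:
    results.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_dataset(dataset: SimulatedDataset, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = dataset.otu_ids
    write_count_table(outdir / "counts.tsv", dataset.y, otu_ids=ids)
    pd.DataFrame({"sample_id": [f"S{i + 1}" for i in range(dataset.n_subjects)],
                  "x": dataset.x}).to_csv(outdir / "covariate.tsv", sep="\t", index=False)
    pd.DataFrame({"sample_id": [f"S{i + 1}" for i in range(dataset.n_subjects)],
                  "N": dataset.N}).to_csv(outdir / "library_sizes.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"otu_id": ids, "eta": dataset.truth.eta, "gamma": dataset.truth.gamma,
         "beta": dataset.truth.beta}
    ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    if dataset.config is not None:
        cfg = {
            "n_subjects": dataset.config.n_subjects,
            "mean_depth": float(dataset.config.mean_depth),
            "sigma_L": float(dataset.config.sigma_L),
            "p_assoc": float(dataset.config.p_assoc),
            "effect_df": float(dataset.config.effect_df),
            "effect_scale": float(dataset.config.effect_scale),
            "seed": int(dataset.config.seed),
            "pi": [float(v) for v in dataset.config.pi],
        }
        (outdir / "config.yaml").write_text(yaml.safe_dump(cfg))
    return outdir


def load_dataset(indir) -> SimulatedDataset:
    indir = Path(indir)
    y, otu_ids, _ = read_count_table(indir / "counts.tsv")
    x = pd.read_csv(indir / "covariate.tsv", sep="\t")["x"].to_numpy(float)
    N = pd.read_csv(indir / "library_sizes.tsv", sep="\t")["N"].to_numpy(np.int64)
    tr = pd.read_csv(indir / "truth.tsv", sep="\t")
    truth = SpikeTruth(
        eta=tr["eta"].to_numpy(int),
        gamma=tr["gamma"].to_numpy(float),
        beta=tr["beta"].to_numpy(float),
    )
    config = None
    cfg_path = indir / "config.yaml"
    if cfg_path.exists():
        raw = yaml.safe_load(cfg_path.read_text())
        config = SimConfig(
            pi=np.asarray(raw["pi"], dtype=float),
            n_subjects=raw["n_subjects"],
            mean_depth=raw["mean_depth"],
            sigma_L=raw["sigma_L"],
            p_assoc=raw["p_assoc"],
            effect_df=raw["effect_df"],
            effect_scale=raw["effect_scale"],
            seed=raw["seed"],
        )
    return SimulatedDataset(x=x, N=N, y=y, truth=truth, config=config)


def write_biom_json(path, y, otu_ids=None, sample_ids=None) -> None:
    """Export counts as a BIOM 1.0 (JSON) OTU table (observations = OTUs)."""
    y = np.asarray(y)
    n, J = y.shape
    otu_ids = [f"OTU{j + 1}" for j in range(J)] if otu_ids is None else list(otu_ids)
    sample_ids = [f"S{i + 1}" for i in range(n)] if sample_ids is None else list(sample_ids)
    rows_j, cols_i = np.nonzero(y.T)
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "dmbench",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [J, n],
        "rows": [{"id": str(o), "metadata": None} for o in otu_ids],
        "columns": [{"id": str(s), "metadata": None} for s in sample_ids],
        "data": [[int(r), int(c), int(y.T[r, c])] for r, c in zip(rows_j, cols_i)],
    }
    Path(path).write_text(json.dumps(doc))


def read_biom_json(path):
    """Import a BIOM 1.0 JSON table; returns (counts, otu_ids, sample_ids)."""
    doc = json.loads(Path(path).read_text())
    J, n = doc["shape"]
    y = np.zeros((n, J), dtype=np.int64)
    if doc["matrix_type"] == "sparse":
        for r, c, v in doc["data"]:
            y[c, r] = v
    else:
        y = np.asarray(doc["data"]).T.astype(np.int64)
    otu_ids = np.array([r["id"] for r in doc["rows"]])
    sample_ids = np.array([c["id"] for c in doc["columns"]])
    return y, otu_ids, sample_ids
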