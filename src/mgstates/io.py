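"""Plain-text IO helpers: MTX matrix directories and GMT gene-set files."""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = ["read_mtx_dir", "write_mtx_dir", "read_gmt", "write_gmt"]


def read_mtx_dir(path) -> ad.AnnData:
    """Read ``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv`` (cells x features).

    The matrix is stored features x cells on disk (the 10x convention) and
    transposed on read.
    """
    path = Path(path)
    x = sp.csr_matrix(scipy.io.mmread(path / "matrix.mtx").T)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    features = pd.read_csv(path / "features.tsv", sep="\t", header=None)
    adata = ad.AnnData(
        X=x,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="cell_barcode")),
        var=pd.DataFrame(index=pd.Index(features[0].astype(str), name="feature")),
    )
    if features.shape[1] > 1:
        adata.var["modality"] = features[1].to_numpy()
    return adata


def write_mtx_dir(adata: ad.AnnData, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    x = sp.coo_matrix(adata.X).T
    scipy.io.mmwrite(str(path / "matrix.mtx"), x)
    pd.Series(adata.obs_names).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)
    var = pd.DataFrame({"feature": adata.var_names})
    if "modality" in adata.var:
        var["modality"] = adata.var["modality"].to_numpy()
    var.to_csv(path / "features.tsv", sep="\t", index=False, header=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: one tab-separated line per set, name, description, genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, genes = fields[0], [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"empty gene list for set {name!r}")
            sets[name] = genes
    if not sets:
        raise ValueError("empty GMT file")
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
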