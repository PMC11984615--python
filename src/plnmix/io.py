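"""Count-matrix containers, readers/writers, and result serialization.

Orientation is fixed as samples x features (rows are observations).  TSV/CSV
files carry a header row of feature ids and a first column of sample ids;
MatrixMarket (.mtx) files are coordinate-integer with sidecar plain-text
label files ``<stem>.rows.txt`` and ``<stem>.cols.txt`` (one id per line).

Counts must be integers: normalized or relative-abundance inputs are
refused — depth differences belong in the offsets mechanism, not in the
counts themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from . import __version__
from .mixture import MixtureFit, ModelSelection
from .variational import MPLNFit

__all__ = ["CountMatrix", "read_counts", "write_counts", "write_results", "read_results"]

RESULTS_SCHEMA_VERSION = 1


@dataclass
class CountMatrix:
    """An (n, d) nonnegative integer count matrix with sample/feature labels
    and optional log-scale offsets (default all zero)."""

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)
    offsets: np.ndarray | None = None

    def __post_init__(self):
        V = np.asarray(self.values)
        if V.ndim != 2:
            raise ValueError("values must be a 2-D samples x features matrix")
        Vf = V.astype(float)
        if np.any(~np.isfinite(Vf)):
            raise ValueError("counts contain NaN or infinite entries")
        if np.any(Vf < 0):
            raise ValueError("counts contain negative entries")
        if np.any(Vf != np.floor(Vf)):
            raise ValueError(
                "counts must be integers; normalized/relative-abundance input "
                "is refused — use offsets for depth normalization instead"
            )
        self.values = Vf.astype(np.int64)
        n, d = self.values.shape
        if not self.sample_ids:
            self.sample_ids = [f"sample_{i + 1}" for i in range(n)]
        if not self.feature_ids:
            self.feature_ids = [f"feature_{j + 1}" for j in range(d)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")
        if len(self.feature_ids) != d:
            raise ValueError("feature_ids length mismatch")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != d:
            raise ValueError("duplicate feature ids")
        if self.offsets is None:
            self.offsets = np.zeros((n, d))
        else:
            O = np.asarray(self.offsets, dtype=float)
            if O.ndim == 1:
                if O.shape[0] != n:
                    raise ValueError("offset vector length mismatch")
                O = np.repeat(O[:, None], d, axis=1)
            elif O.shape != (n, d):
                raise ValueError(f"offsets shape {O.shape} != ({n}, {d})")
            self.offsets = O

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"tsv", "csv", "mtx"}:
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_counts(path, format: str | None = None, transpose: bool = False) -> CountMatrix:
    """Read a count matrix from TSV/CSV (header = feature ids, first column =
    sample ids) or MatrixMarket with sidecar label files.  Non-integer,
    negative, or NaN entries and duplicate ids each raise a distinct error."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt in {"tsv", "csv"}:
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.columns.size == 0:
            raise ValueError(f"{path.name}: malformed header (no feature columns)")
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"{path.name}: non-numeric entries: {exc}") from exc
        sample_ids = [str(s) for s in df.index]
        feature_ids = [str(c) for c in df.columns]
    elif fmt == "mtx":
        mat = spio.mmread(path)
        values = np.asarray(
            mat.toarray() if sparse.issparse(mat) else mat, dtype=float
        )
        stem = path.with_suffix("")
        rows_file = stem.with_suffix(".rows.txt")
        cols_file = stem.with_suffix(".cols.txt")
        sample_ids = (
            rows_file.read_text().split() if rows_file.exists() else []
        )
        feature_ids = (
            cols_file.read_text().split() if cols_file.exists() else []
        )
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    if transpose:
        values = values.T
        sample_ids, feature_ids = feature_ids, sample_ids
    return CountMatrix(values, list(sample_ids), list(feature_ids))


def write_counts(cm: CountMatrix, path, format: str | None = None) -> None:
    """Write a count matrix as TSV/CSV (or MatrixMarket with sidecars)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt in {"tsv", "csv"}:
        sep = "\t" if fmt == "tsv" else ","
        df = pd.DataFrame(cm.values, index=cm.sample_ids, columns=cm.feature_ids)
        df.to_csv(path, sep=sep)
    elif fmt == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(cm.values), field="integer")
        stem = path.with_suffix("")
        stem.with_suffix(".rows.txt").write_text("\n".join(cm.sample_ids) + "\n")
        stem.with_suffix(".cols.txt").write_text("\n".join(cm.feature_ids) + "\n")
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def _params_dict(params) -> dict:
    return {"mu": params.mu.tolist(), "Sigma": params.Sigma.tolist()}


def _fit_payload(obj) -> dict:
    if isinstance(obj, MPLNFit):
        return {
            "type": "mpln_fit",
            "params": _params_dict(obj.params),
            "elbo": obj.elbo,
            "n_iter": obj.n_iter,
            "converged": obj.converged,
        }
    if isinstance(obj, MixtureFit):
        return {
            "type": "mixture_fit",
            "G": obj.G,
            "pi": obj.pi.tolist(),
            "components": [_params_dict(c) for c in obj.components],
            "elbo": obj.elbo,
            "bic": obj.bic,
            "labels": obj.labels.tolist(),
            "converged": obj.converged,
        }
    if isinstance(obj, ModelSelection):
        return {
            "type": "model_selection",
            "criterion": obj.criterion,
            "chosen_G": obj.chosen_G,
            "bic_table": [
                {"G": G, "bic": obj.fits[G].bic} for G in sorted(obj.fits)
            ],
            "best": _fit_payload(obj.best),
        }
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def write_results(obj, path, seed=None, extra: dict | None = None) -> dict:
    """Serialize a fit or model selection to schema-versioned JSON and return
    the document."""
    doc = {
        "schema_version": RESULTS_SCHEMA_VERSION,
        "software": {"name": "plnmix", "version": __version__},
        "seed": seed,
    }
    doc.update(_fit_payload(obj))
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
    return doc


def read_results(path) -> dict:
    """Read and validate a results JSON document."""
    doc = json.loads(Path(path).read_text())
    for key in ("schema_version", "software", "seed", "type"):
        if key not in doc:
            raise ValueError(f"results document missing required field {key!r}")
    return doc
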