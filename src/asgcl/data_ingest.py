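"""Reading, aligning, filtering and binarizing cell-line / drug response tables.

Input tables are delimited text matrices: first row = column identifiers,
first column = row identifiers.  Cell-line omics layers (gene expression,
copy-number variation, somatic mutation) are real matrices over cell lines;
drug features are binary molecular-fingerprint matrices over compounds; the
response table holds log-scale IC50 measurements with missing entries for
unscreened cell-line/drug pairs.

Binarization follows the two conventions used by the public pharmacogenomic
screens: a per-drug IC50 threshold table (GDSC style) or a global z-score
cutoff on log10(IC50) (CCLE style, sensitive when z < -0.8).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OmicsTable", "DrugTable", "ResponseTable", "LabelRule", "Dataset",
    "read_matrix", "align_and_filter", "binarize_ccle", "binarize_gdsc",
]


@dataclass
class OmicsTable:
    """One omics layer: real-valued features over cell lines."""
    layer_name: str
    frame: pd.DataFrame  # cell lines x features

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def row_ids(self) -> list:
        return list(self.frame.index)


@dataclass
class DrugTable:
    """Binary fingerprint bits over drugs (compound IDs as row ids)."""
    frame: pd.DataFrame  # drugs x fingerprint bits

    def __post_init__(self):
        vals = self.frame.to_numpy(dtype=float)
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("drug fingerprint entries must be 0/1")

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def row_ids(self) -> list:
        return list(self.frame.index)


@dataclass
class ResponseTable:
    """Observed cell-line x drug responses with binary labels.

    ``labels`` is meaningful only where ``observed`` is True; ``raw`` holds
    the continuous (log-IC50 scale) measurements when available.
    """
    labels: np.ndarray            # {0,1}, cell lines x drugs
    observed: np.ndarray          # bool mask, same shape
    cell_ids: list
    drug_ids: list
    raw: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.labels.shape != self.observed.shape:
            raise ValueError("labels and observed mask must share a shape")
        lab = self.labels[self.observed]
        if lab.size and not np.isin(lab, (0, 1)).all():
            raise ValueError("labels must be binary on observed entries")

    @property
    def shape(self):
        return self.labels.shape

    def observed_pairs(self) -> np.ndarray:
        """(n_obs, 3) array of (cell index, drug index, label)."""
        ci, dj = np.nonzero(self.observed)
        return np.column_stack([ci, dj, self.labels[ci, dj]])


@dataclass
class LabelRule:
    """How continuous responses are turned into sensitive/resistant labels."""
    mode: Literal["gdsc_threshold", "ccle_zscore"] = "ccle_zscore"
    per_drug_thresholds: pd.Series | None = None
    z_cutoff: float = -0.8
    direction: Literal["below", "above"] = "below"
    per_drug_zscore: bool = False

    def __post_init__(self):
        if not np.isfinite(self.z_cutoff):
            raise ValueError("z_cutoff must be finite")
        if self.direction not in ("below", "above"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class Dataset:
    """Canonical aligned dataset: omics layers, fingerprints, responses."""
    omics: list[OmicsTable]
    drugs: DrugTable
    responses: ResponseTable
    meta: dict = field(default_factory=dict)

    @property
    def cell_ids(self) -> list:
        return self.responses.cell_ids

    @property
    def drug_ids(self) -> list:
        return self.responses.drug_ids

    def cell_features(self) -> np.ndarray:
        """All omics layers concatenated feature-wise (cells x sum of dims)."""
        return np.concatenate([o.values for o in self.omics], axis=1)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.17g"  # round-trips float64 exactly
        for o in self.omics:
            o.frame.to_csv(out / f"omics_{o.layer_name}.csv", float_format=fmt)
        self.drugs.frame.to_csv(out / "drug_fingerprints.csv", float_format=fmt)
        lab = pd.DataFrame(
            np.where(self.responses.observed, self.responses.labels.astype(float), np.nan),
            index=self.cell_ids, columns=self.drug_ids)
        lab.to_csv(out / "response_labels.csv", float_format=fmt)
        if self.responses.raw is not None:
            pd.DataFrame(self.responses.raw, index=self.cell_ids,
                         columns=self.drug_ids).to_csv(out / "response_raw.csv",
                                                       float_format=fmt)
        manifest = {
            "cell_ids": [str(c) for c in self.cell_ids],
            "drug_ids": [str(d) for d in self.drug_ids],
            "omics_layers": [o.layer_name for o in self.omics],
            "has_raw": self.responses.raw is not None,
            **self.meta,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, in_dir: str | Path) -> "Dataset":
        src = Path(in_dir)
        manifest = json.loads((src / "manifest.json").read_text())
        omics = [OmicsTable(name, read_matrix(src / f"omics_{name}.csv"))
                 for name in manifest["omics_layers"]]
        drugs = DrugTable(read_matrix(src / "drug_fingerprints.csv"))
        lab = read_matrix(src / "response_labels.csv", allow_missing=True)
        observed = lab.notna().to_numpy()
        labels = np.where(observed, lab.to_numpy(dtype=float), 0).astype(np.int8)
        raw = None
        if manifest.get("has_raw"):
            raw = read_matrix(src / "response_raw.csv", allow_missing=True).to_numpy(dtype=float)
        resp = ResponseTable(labels, observed, list(lab.index), list(lab.columns), raw=raw)
        meta = {k: v for k, v in manifest.items()
                if k not in ("cell_ids", "drug_ids", "omics_layers", "has_raw")}
        return cls(omics, drugs, resp, meta)


def read_matrix(path: str | Path, delimiter: str | None = None,
                allow_missing: bool = False) -> pd.DataFrame:
    """Read a delimited matrix with row/column identifiers.

    The delimiter is inferred from the file extension when not given
    (``.tsv``/``.txt`` -> tab, otherwise comma).  Raises on ragged rows,
    malformed numeric cells and duplicate identifiers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate row identifiers in {path.name}: {dups}")
    if df.columns.has_duplicates:
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValueError(f"duplicate column identifiers in {path.name}: {dups}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            # astype(float) parses via float(), which round-trips exactly
            out[col] = df[col].astype(float)
        except (ValueError, TypeError):
            for row, cell in df[col].items():
                try:
                    float(cell)
                except (ValueError, TypeError):
                    raise ValueError(
                        f"malformed numeric cell at row {row!r}, column {col!r} "
                        f"in {path.name}: {cell!r}") from None
            raise
    if not allow_missing and out.isna().to_numpy().any():
        row, col = np.argwhere(out.isna().to_numpy())[0]
        raise ValueError(f"missing value at row {out.index[row]!r}, "
                         f"column {out.columns[col]!r} in {path.name}")
    return out


def _dedup_first(frame: pd.DataFrame) -> pd.DataFrame:
    return frame[~frame.index.duplicated(keep="first")]


def align_and_filter(omics: Sequence[OmicsTable], drugs: DrugTable,
                     responses: ResponseTable) -> Dataset:
    """Intersect identifier namespaces and re-index everything consistently.

    Cell lines must be present (with complete data) in every omics layer and
    in the response table; drugs sharing a compound ID keep the first
    occurrence.  Omics rows containing missing values are dropped.
    """
    frames = []
    for o in omics:
        f = _dedup_first(o.frame)
        f = f[f.notna().all(axis=1)]  # drop cell lines lacking this layer
        frames.append(OmicsTable(o.layer_name, f))

    cells = [c for c in responses.cell_ids]
    keep_cells = [c for c in cells
                  if all(c in f.frame.index for f in frames)]
    if not keep_cells:
        raise ValueError("no cell line is present in all omics layers "
                         "and the response table")

    drug_frame = _dedup_first(drugs.frame)
    keep_drugs = [d for d in responses.drug_ids if d in drug_frame.index]
    if not keep_drugs:
        raise ValueError("no drug is shared between the fingerprint table "
                         "and the response table")

    ci = [responses.cell_ids.index(c) for c in keep_cells]
    dj = [responses.drug_ids.index(d) for d in keep_drugs]
    resp = ResponseTable(
        responses.labels[np.ix_(ci, dj)],
        responses.observed[np.ix_(ci, dj)],
        keep_cells, keep_drugs,
        raw=None if responses.raw is None else responses.raw[np.ix_(ci, dj)])
    aligned_omics = [OmicsTable(f.layer_name, f.frame.loc[keep_cells])
                     for f in frames]
    aligned_drugs = DrugTable(drug_frame.loc[keep_drugs])
    return Dataset(aligned_omics, aligned_drugs, resp)


def binarize_ccle(raw: pd.DataFrame, z_cutoff: float = -0.8,
                  per_drug: bool = False) -> ResponseTable:
    """Label responses by z-scoring log10(IC50) and thresholding.

    z-scores use the population standard deviation over all observed entries
    jointly (or per drug column with ``per_drug=True``); entries with
    z < ``z_cutoff`` are labeled sensitive (1).
    """
    values = raw.to_numpy(dtype=float)
    observed = np.isfinite(values)
    obs = values[observed]
    if obs.size < 2:
        raise ValueError("need at least 2 observed values to standardize")
    if per_drug:
        z = np.full_like(values, np.nan)
        for j in range(values.shape[1]):
            col = values[:, j]
            m = np.isfinite(col)
            if m.sum() >= 2:
                sd = col[m].std()
                if sd == 0:
                    raise ValueError(f"zero variance in drug column {raw.columns[j]!r}")
                z[m, j] = (col[m] - col[m].mean()) / sd
    else:
        sd = obs.std()  # population sd
        if sd == 0:
            raise ValueError("zero variance: cannot standardize responses")
        z = (values - obs.mean()) / sd
    labels = np.where(observed & (z < z_cutoff), 1, 0)
    return ResponseTable(labels, observed, list(raw.index), list(raw.columns),
                         raw=values)


def binarize_gdsc(raw: pd.DataFrame, rule: LabelRule) -> ResponseTable:
    """Label responses by comparing IC50 to a per-drug threshold table.

    ``rule.direction`` controls which side of the threshold is sensitive:
    ``below`` (pharmacological convention, low IC50 = sensitive, the default)
    or ``above``.  The comparison is strict; values equal to the threshold
    are labeled resistant under either direction.  The threshold table and
    response table are assumed to be on the same (raw or log) IC50 scale.
    """
    if rule.per_drug_thresholds is None:
        raise ValueError("gdsc_threshold mode requires per_drug_thresholds")
    thresholds = rule.per_drug_thresholds
    missing = [d for d in raw.columns if d not in thresholds.index]
    if missing:
        raise ValueError(f"drugs without a threshold: {missing}")
    values = raw.to_numpy(dtype=float)
    observed = np.isfinite(values)
    thr = thresholds.loc[raw.columns].to_numpy(dtype=float)[None, :]
    if rule.direction == "below":
        sens = values < thr
    else:
        sens = values > thr
    labels = np.where(observed & sens, 1, 0)
    return ResponseTable(labels, observed, list(raw.index), list(raw.columns),
                         raw=values)
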