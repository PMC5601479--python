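"""Right-censored survival data: container, I/O, preprocessing, splitting, merging.

The central container is :class:`SurvivalDataset`, which keeps a feature table
(rows = patients, columns = named features) aligned with a survival/follow-up
time vector and a binary event indicator (1 = event observed, 0 =
right-censored).  Preprocessing follows the conventions common for training
neural survival models on molecular cohorts: categorical expansion to binary
indicators, mean imputation for designated binary clinical features,
1-nearest-neighbour imputation for sparsely missing molecular features with a
drop threshold, and standardization to zero mean / unit variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalDataset",
    "SplitAssignment",
    "SchemaError",
    "ValidationError",
    "STAGE_ALIASES",
    "load_dataset",
    "expand_categorical",
    "impute_mean",
    "impute_knn",
    "standardize",
    "apply_standardization",
    "split_train_val_test",
    "merge_datasets",
]

#: Example alias map unifying pathologic/clinical staging variables across
#: cohorts prior to a shared-feature merge.
STAGE_ALIASES = {"pathologic_stage": "stage", "clinical_stage": "stage"}

#: Accepted spellings of the event indicator (case-insensitive for strings).
EVENT_CODES = {
    "0": 0.0, "1": 1.0, "0.0": 0.0, "1.0": 1.0,
    "true": 1.0, "false": 0.0,
    "dead": 1.0, "alive": 0.0,
}

MISSING_MARKERS = ["", "NA", "NaN", "nan"]


class SchemaError(ValueError):
    """A required column is absent or the file layout is unusable."""


class ValidationError(ValueError):
    """Column contents violate the survival-data contract."""


@dataclass
class SurvivalDataset:
    """Feature matrix with aligned survival times and event indicators.

    Parameters
    ----------
    features : pandas.DataFrame
        n patients x N features; the index holds unique patient identifiers.
        Categorical (string-valued) columns may be present before
        :func:`expand_categorical`; missing values may be present before
        imputation.
    times : ndarray of float
        Non-negative survival or follow-up times.
    events : ndarray of float
        1.0 = event observed (patient is in the uncensored set), 0.0 =
        right-censored.
    feature_kinds : dict
        Per-feature tag in {"numeric", "categorical", "binary-expanded",
        "clinical-binary"}.
    provenance : ndarray of str, optional
        Per-patient origin label, populated by :func:`merge_datasets`; kept
        outside the feature matrix.
    """

    features: pd.DataFrame
    times: np.ndarray
    events: np.ndarray
    feature_kinds: dict = field(default_factory=dict)
    provenance: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=float)
        n = len(self.features)
        if n < 2:
            raise ValidationError(f"need at least 2 patients, got {n}")
        if len(self.times) != n or len(self.events) != n:
            raise ValidationError("times/events not aligned with features")
        if np.any(np.isnan(self.times)) or np.any(self.times < 0):
            raise ValidationError("times must be non-negative and non-missing")
        if not np.all(np.isin(self.events, (0.0, 1.0))):
            bad = sorted(set(self.events) - {0.0, 1.0})
            raise ValidationError(f"event indicator must be 0/1, found {bad}")
        if self.features.index.duplicated().any():
            raise ValidationError("duplicate patient ids")
        if self.features.columns.duplicated().any():
            raise ValidationError("duplicate feature names")
        if not self.feature_kinds:
            self.feature_kinds = {c: "numeric" for c in self.features.columns}
        if self.provenance is not None and len(self.provenance) != n:
            raise ValidationError("provenance not aligned with features")

    @property
    def n(self) -> int:
        return len(self.features)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def patient_ids(self) -> np.ndarray:
        return self.features.index.to_numpy()

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def X(self) -> np.ndarray:
        """Numeric feature matrix (raises if categorical columns remain)."""
        cats = [c for c, k in self.feature_kinds.items() if k == "categorical"]
        if cats:
            raise ValidationError(
                f"categorical columns not yet expanded: {cats}")
        return self.features.to_numpy(dtype=float)

    def subset(self, idx) -> "SurvivalDataset":
        """Row subset by positional index, preserving alignment."""
        idx = np.asarray(idx)
        return SurvivalDataset(
            features=self.features.iloc[idx].copy(),
            times=self.times[idx],
            events=self.events[idx],
            feature_kinds=dict(self.feature_kinds),
            provenance=None if self.provenance is None else self.provenance[idx],
        )

    def with_features(self, features: pd.DataFrame, kinds: dict) -> "SurvivalDataset":
        return SurvivalDataset(
            features=features, times=self.times.copy(),
            events=self.events.copy(), feature_kinds=kinds,
            provenance=None if self.provenance is None else self.provenance.copy(),
        )

    def to_frame(self, time_col="time", event_col="event") -> pd.DataFrame:
        out = self.features.copy()
        out.insert(0, event_col, self.events.astype(int))
        out.insert(0, time_col, self.times)
        if self.provenance is not None:
            out["__origin__"] = self.provenance
        return out

    def write(self, path, time_col="time", event_col="event", delimiter="\t"):
        self.to_frame(time_col, event_col).to_csv(
            path, sep=delimiter, index_label="patient_id")


@dataclass
class SplitAssignment:
    """Disjoint train/validation/test index sets covering all patients.

    Sizes follow the 60/20/20 protocol: ``|train| = round(0.6 n)``,
    ``|val| = round(0.2 n)`` and the remainder goes to test.
    """

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    def __post_init__(self):
        n = self.n
        all_idx = np.concatenate([self.train_idx, self.val_idx, self.test_idx])
        if len(np.unique(all_idx)) != n or set(all_idx) != set(range(n)):
            raise ValidationError("split does not partition 0..n-1")

    @property
    def n(self) -> int:
        return len(self.train_idx) + len(self.val_idx) + len(self.test_idx)

    def write(self, path, patient_ids=None):
        """Serialize as a two-column id -> split TSV."""
        ids = np.arange(self.n) if patient_ids is None else np.asarray(patient_ids)
        rows = []
        for name, idx in (("train", self.train_idx), ("val", self.val_idx),
                          ("test", self.test_idx)):
            rows += [(ids[i], name) for i in idx]
        pd.DataFrame(rows, columns=["patient_id", "split"]).to_csv(
            path, sep="\t", index=False)


def load_dataset(path, time_col, event_col, id_col=None, delimiter="\t") -> SurvivalDataset:
    """Read a delimited text table into a :class:`SurvivalDataset`.

    All columns other than the time, event and optional id columns become
    features.  Non-numeric columns are tagged ``categorical`` and left for
    :func:`expand_categorical`; missing cells (empty, ``NA``, ``NaN``) are
    preserved as NaN for the imputation steps.
    """
    df = pd.read_csv(path, sep=delimiter, na_values=MISSING_MARKERS,
                     keep_default_na=False)
    for col in (time_col, event_col):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} not in {list(df.columns)}")
    if id_col is not None:
        if id_col not in df.columns:
            raise SchemaError(f"id column {id_col!r} not found")
        df = df.set_index(id_col)
    else:
        df.index = pd.RangeIndex(len(df))

    times = pd.to_numeric(df[time_col], errors="coerce").to_numpy()
    if np.any(np.isnan(times)):
        raise ValidationError(f"non-numeric or missing values in {time_col!r}")
    if np.any(times < 0):
        raise ValidationError(f"negative times in {time_col!r}")

    events = _parse_events(df[event_col])

    feats = df.drop(columns=[time_col, event_col])
    kinds = {}
    for c in feats.columns:
        numeric = pd.to_numeric(feats[c], errors="coerce")
        observed = feats[c].notna()
        if (numeric.notna() | ~observed).all():
            feats[c] = numeric
            kinds[c] = "numeric"
        else:
            kinds[c] = "categorical"
    return SurvivalDataset(features=feats, times=times, events=events,
                           feature_kinds=kinds)


def _parse_events(col: pd.Series) -> np.ndarray:
    out = np.empty(len(col), dtype=float)
    for i, v in enumerate(col):
        if pd.isna(v):
            raise ValidationError("missing event indicator")
        key = str(v).strip().lower()
        if key not in EVENT_CODES:
            raise ValidationError(
                f"event value {v!r} not in accepted codes "
                "{0,1,TRUE,FALSE,dead,alive}")
        out[i] = EVENT_CODES[key]
    return out


def expand_categorical(ds: SurvivalDataset) -> SurvivalDataset:
    """Replace each categorical column with one binary indicator per level.

    A column with k observed levels becomes k columns named ``<col>=<level>``.
    Rows missing the original value are missing in every indicator.
    Single-level columns carry no information and are dropped with a warning.
    """
    feats = ds.features.copy()
    kinds = dict(ds.feature_kinds)
    for col in [c for c, k in ds.feature_kinds.items() if k == "categorical"]:
        levels = sorted(feats[col].dropna().unique(), key=str)
        if len(levels) <= 1:
            warnings.warn(f"dropping single-level categorical column {col!r}")
            feats = feats.drop(columns=[col])
            del kinds[col]
            continue
        observed = feats[col].notna()
        pos = feats.columns.get_loc(col)
        feats = feats.drop(columns=[col])
        del kinds[col]
        for j, level in enumerate(levels):
            name = f"{col}={level}"
            vals = (ds.features[col] == level).astype(float)
            vals[~observed] = np.nan
            feats.insert(pos + j, name, vals)
            kinds[name] = "binary-expanded"
    return ds.with_features(feats, kinds)


def impute_mean(ds: SurvivalDataset, cols) -> SurvivalDataset:
    """Fill missing entries in the named columns with the observed column mean.

    For a binary column the mean is the observed prevalence, so the imputed
    value reflects the prior likelihood of the positive state.  Imputed
    columns are tagged ``clinical-binary`` when their observed values are
    binary.
    """
    feats = ds.features.copy()
    kinds = dict(ds.feature_kinds)
    for col in cols:
        if col not in feats.columns:
            raise SchemaError(f"column {col!r} not found")
        observed = feats[col].dropna()
        if observed.empty:
            raise ValidationError(f"column {col!r} is entirely missing")
        feats[col] = feats[col].fillna(float(observed.mean()))
        if set(np.unique(observed.to_numpy(dtype=float))) <= {0.0, 1.0}:
            kinds[col] = "clinical-binary"
    return ds.with_features(feats, kinds)


def impute_knn(ds: SurvivalDataset, max_missing_frac: float = 0.20) -> SurvivalDataset:
    """1-nearest-neighbour imputation with a missingness drop threshold.

    Features missing in ``>= max_missing_frac`` of patients are discarded.
    Each remaining missing cell is filled with that feature's value in the
    single nearest patient, measured by Euclidean distance over the features
    observed in both patients.  When no patient both observes the feature and
    shares an observed feature, the column mean is used and a message logged.
    """
    cats = [c for c, k in ds.feature_kinds.items() if k == "categorical"]
    if cats:
        raise ValidationError(f"expand categorical columns first: {cats}")
    feats = ds.features.copy()
    kinds = dict(ds.feature_kinds)

    frac = feats.isna().mean(axis=0)
    dropped = list(feats.columns[frac >= max_missing_frac])
    if dropped:
        logger.info("impute_knn: dropping %d features with >= %.0f%% missing: %s",
                    len(dropped), 100 * max_missing_frac, dropped)
        feats = feats.drop(columns=dropped)
        for c in dropped:
            del kinds[c]

    M = feats.to_numpy(dtype=float)
    obs = ~np.isnan(M)
    if not obs.all(axis=0).any():
        raise ValidationError("no fully observed feature available for distances")
    filled = M.copy()
    miss_rows, miss_cols = np.where(~obs)
    for i in set(miss_rows):
        cols_i = miss_cols[miss_rows == i]
        # distance from patient i to every other patient over shared features
        shared = obs & obs[i]  # (n, p) features observed in both
        diff2 = np.where(shared, (M - M[i]) ** 2, 0.0)
        with np.errstate(invalid="ignore"):
            dist = np.sqrt(np.nansum(diff2, axis=1))
        dist[i] = np.inf
        dist[~shared.any(axis=1)] = np.inf
        for j in cols_i:
            cand = dist.copy()
            cand[~obs[:, j]] = np.inf
            k = int(np.argmin(cand))
            if np.isinf(cand[k]):
                colmean = np.nanmean(M[:, j])
                logger.info("impute_knn: no neighbour for patient %d feature %s;"
                            " falling back to column mean", i, feats.columns[j])
                filled[i, j] = colmean
            else:
                filled[i, j] = M[k, j]
    out = pd.DataFrame(filled, index=feats.index, columns=feats.columns)
    return ds.with_features(out, kinds)


def standardize(ds: SurvivalDataset):
    """Scale every feature to zero mean and unit variance (divisor n).

    Returns the transformed dataset and a record of per-feature means and
    scales so that validation/test data can be transformed with training
    statistics via :func:`apply_standardization`.  Zero-variance columns are
    dropped with a warning.
    """
    X = ds.X
    mean = X.mean(axis=0)
    scale = X.std(axis=0)  # population convention, ddof=0
    keep = scale > 0
    if not keep.all():
        warnings.warn(f"dropping zero-variance columns: "
                      f"{list(np.array(ds.feature_names)[~keep])}")
    names = list(np.array(ds.feature_names)[keep])
    record = pd.DataFrame({"mean": mean[keep], "scale": scale[keep]}, index=names)
    Z = (X[:, keep] - mean[keep]) / scale[keep]
    feats = pd.DataFrame(Z, index=ds.features.index, columns=names)
    kinds = {c: ds.feature_kinds[c] for c in names}
    return ds.with_features(feats, kinds), record


def apply_standardization(ds: SurvivalDataset, record: pd.DataFrame) -> SurvivalDataset:
    """Transform a dataset with previously computed means and scales."""
    missing = [c for c in record.index if c not in ds.features.columns]
    if missing:
        raise SchemaError(f"dataset lacks standardized features: {missing}")
    X = ds.features[record.index].to_numpy(dtype=float)
    Z = (X - record["mean"].to_numpy()) / record["scale"].to_numpy()
    feats = pd.DataFrame(Z, index=ds.features.index, columns=record.index)
    kinds = {c: ds.feature_kinds[c] for c in record.index}
    return ds.with_features(feats, kinds)


def split_train_val_test(ds: SurvivalDataset, seed: int) -> SplitAssignment:
    """Randomize patients to 60% training / 20% validation / 20% testing.

    Uniformly random permutation for the given seed; |train| = round(0.6 n),
    |val| = round(0.2 n), remainder to test.  Deterministic per seed.
    """
    n = ds.n
    if n < 5:
        raise ValidationError(f"need n >= 5 to split, got {n}")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = round(0.6 * n)
    n_val = round(0.2 * n)
    return SplitAssignment(
        train_idx=np.sort(perm[:n_train]),
        val_idx=np.sort(perm[n_train:n_train + n_val]),
        test_idx=np.sort(perm[n_train + n_val:]),
        seed=seed,
    )


def merge_datasets(datasets, alias_map=None, origins=None) -> SurvivalDataset:
    """Row-concatenate cohorts on their shared features.

    Feature names are first renamed through ``alias_map`` (for example
    :data:`STAGE_ALIASES`, which unifies pathologic and clinical stage as a
    single "stage" variable); the merged feature set is the intersection of
    the renamed names, in the order of the first dataset.  Per-patient origin
    is recorded in the ``provenance`` attribute, outside the feature matrix.
    No re-normalization is applied.
    """
    if len(datasets) < 2:
        raise ValidationError("merge needs at least 2 datasets")
    alias_map = alias_map or {}
    if origins is None:
        origins = [f"dataset{i}" for i in range(len(datasets))]

    renamed = []
    for ds in datasets:
        feats = ds.features.rename(columns=alias_map)
        if feats.columns.duplicated().any():
            raise ValidationError("alias map produces duplicate feature names "
                                  "within one dataset")
        renamed.append(feats)

    shared = [c for c in renamed[0].columns
              if all(c in f.columns for f in renamed[1:])]
    if not shared:
        raise ValidationError("datasets share no features")

    ids = np.concatenate([f.index.to_numpy() for f in renamed])
    if len(np.unique(ids)) != len(ids):
        raise ValidationError("duplicate patient ids across datasets")

    feats = pd.concat([f[shared] for f in renamed], axis=0)
    times = np.concatenate([ds.times for ds in datasets])
    events = np.concatenate([ds.events for ds in datasets])
    provenance = np.concatenate([
        np.full(ds.n, origin) for ds, origin in zip(datasets, origins)])

    ref_kinds = {}
    for ds in datasets:
        for old, kind in ds.feature_kinds.items():
            ref_kinds.setdefault(alias_map.get(old, old), kind)
    kinds = {c: ref_kinds[c] for c in shared}
    return SurvivalDataset(features=feats, times=times, events=events,
                           feature_kinds=kinds, provenance=provenance)
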