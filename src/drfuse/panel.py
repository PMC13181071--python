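"""Score panels: per-sample class-1 probabilities from a bank of base classifiers.

A :class:`ScorePanel` is the common currency of every fusion operator. It holds
an ``(n, m)`` matrix of class-1 (disease) probabilities, one column per base
classifier, plus an optional ``(n, m, 2)`` panel of raw pre-softmax logit
pairs for logit-level fusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, InvalidInputError

__all__ = ["ScorePanel", "read_labels_csv", "write_labels_csv"]


@dataclass(frozen=True)
class ScorePanel:
    """Panel of per-classifier class-1 probabilities (and optional logits).

    Parameters
    ----------
    probs
        ``(n, m)`` array of class-1 probabilities, each in ``[0, 1]``.
    sample_ids
        ``n`` sample identifiers. Defaults to ``s000000 ...``.
    classifier_ids
        ``m`` classifier names. Defaults to ``clf_1 ...``.
    logits
        Optional ``(n, m, 2)`` array of raw ``(class-0, class-1)`` logit
        pairs; the two-class softmax of a pair should reproduce the
        corresponding probability.
    """

    probs: np.ndarray
    sample_ids: tuple = field(default=None)
    classifier_ids: tuple = field(default=None)
    logits: np.ndarray = field(default=None)

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.size == 0:
            raise InvalidInputError("probs must be a non-empty (n, m) matrix")
        if not np.all(np.isfinite(probs)):
            raise InvalidInputError("probabilities must be finite")
        if probs.min() < 0.0 or probs.max() > 1.0:
            raise InvalidInputError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "probs", probs)

        n, m = probs.shape
        sample_ids = self.sample_ids
        if sample_ids is None:
            sample_ids = tuple(f"s{i:06d}" for i in range(n))
        else:
            sample_ids = tuple(str(s) for s in sample_ids)
            if len(sample_ids) != n:
                raise InvalidInputError("sample_ids length does not match probs")
        object.__setattr__(self, "sample_ids", sample_ids)

        classifier_ids = self.classifier_ids
        if classifier_ids is None:
            classifier_ids = tuple(f"clf_{j + 1}" for j in range(m))
        else:
            classifier_ids = tuple(str(c) for c in classifier_ids)
            if len(classifier_ids) != m:
                raise InvalidInputError("classifier_ids length does not match probs")
        object.__setattr__(self, "classifier_ids", classifier_ids)

        if self.logits is not None:
            logits = np.asarray(self.logits, dtype=float)
            if logits.shape != (n, m, 2):
                raise InvalidInputError(
                    f"logits must have shape {(n, m, 2)}, got {logits.shape}"
                )
            if not np.all(np.isfinite(logits)):
                raise InvalidInputError("logits must be finite")
            object.__setattr__(self, "logits", logits)

    @property
    def n_samples(self) -> int:
        return self.probs.shape[0]

    @property
    def n_classifiers(self) -> int:
        return self.probs.shape[1]

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, columns=list(self.classifier_ids))
        df.insert(0, "sample_id", list(self.sample_ids))
        return df

    def logits_to_frame(self) -> pd.DataFrame:
        if self.logits is None:
            raise InvalidInputError("panel has no logits")
        cols = {"sample_id": list(self.sample_ids)}
        for j, name in enumerate(self.classifier_ids):
            cols[f"{name}_logit0"] = self.logits[:, j, 0]
            cols[f"{name}_logit1"] = self.logits[:, j, 1]
        return pd.DataFrame(cols)

    def to_csv(self, path, logits_path=None) -> None:
        """Write the probability panel (and optionally the logit panel) as CSV."""
        self.to_frame().to_csv(path, index=False, float_format="%.10g")
        if logits_path is not None:
            self.logits_to_frame().to_csv(logits_path, index=False, float_format="%.10g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, logits_df: pd.DataFrame = None) -> "ScorePanel":
        if "sample_id" not in df.columns:
            raise DataError("score panel needs a 'sample_id' column")
        clf_cols = [c for c in df.columns if c != "sample_id"]
        if not clf_cols:
            raise DataError("score panel has no classifier columns")
        probs = df[clf_cols].to_numpy(dtype=float)
        logits = None
        if logits_df is not None:
            logits = np.empty((len(df), len(clf_cols), 2))
            for j, name in enumerate(clf_cols):
                try:
                    logits[:, j, 0] = logits_df[f"{name}_logit0"].to_numpy(dtype=float)
                    logits[:, j, 1] = logits_df[f"{name}_logit1"].to_numpy(dtype=float)
                except KeyError as exc:
                    raise DataError(f"logit panel missing column for {name!r}") from exc
        return cls(
            probs,
            sample_ids=tuple(df["sample_id"].astype(str)),
            classifier_ids=tuple(clf_cols),
            logits=logits,
        )

    @classmethod
    def from_csv(cls, path, logits_path=None) -> "ScorePanel":
        """Read ``sample_id, <clf_1>, ..., <clf_m>`` CSV (TSV autodetected)."""
        df = pd.read_csv(path, sep=None, engine="python")
        logits_df = None
        if logits_path is not None:
            logits_df = pd.read_csv(logits_path, sep=None, engine="python")
        try:
            return cls.from_frame(df, logits_df)
        except InvalidInputError as exc:
            raise DataError(str(exc)) from exc


def read_labels_csv(path) -> np.ndarray:
    """Read a ``sample_id,label`` CSV into a 0/1 integer vector."""
    df = pd.read_csv(path, sep=None, engine="python")
    if "label" not in df.columns:
        raise DataError("labels file needs a 'label' column")
    labels = df["label"].to_numpy()
    if not np.isin(labels, (0, 1)).all():
        raise DataError("labels must be 0 (No_DR) or 1 (DR)")
    return labels.astype(int)


def write_labels_csv(path, labels, sample_ids=None) -> None:
    labels = np.asarray(labels, dtype=int)
    if sample_ids is None:
        sample_ids = [f"s{i:06d}" for i in range(len(labels))]
    pd.DataFrame({"sample_id": list(sample_ids), "label": labels}).to_csv(path, index=False)
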