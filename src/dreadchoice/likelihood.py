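"""Softmax choice rule and dataset log-likelihood.

The probability of choosing option i over option j is logistic in the value
difference, p(i over j) = 1 / (1 + exp(-beta * (v_i - v_j))).  Only the
difference matters: adding a constant to both option values (e.g. dread
carried over from earlier, still-pending choices) leaves every choice
probability unchanged, which is what licenses fitting interleaved-design
choices independently.  Likewise the likelihood is invariant to jointly
rescaling beta by c and all values by 1/c, so beta is only interpretable
relative to the utility scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .designs import ChoiceOption, ChoicePair, pairs_to_frame
from .valuation import ModelParams, ModelSpec, WeibullUtilityParams, pair_value_difference

__all__ = [
    "ChoiceDataset",
    "choice_probability",
    "log_choice_probability",
    "dataset_loglik",
    "per_record_probabilities",
    "read_choice_csv",
    "write_choice_csv",
]


@dataclass
class ChoiceDataset:
    """One subject x frame's sequence of binary choices.

    Stored columnar for fast likelihood evaluation: magnitudes and delays of
    the sooner/later options plus the observed choice (0 = sooner,
    1 = later).
    """

    subject_id: str
    frame: str
    x_sooner: np.ndarray
    x_later: np.ndarray
    t_sooner: np.ndarray
    t_later: np.ndarray
    choice: np.ndarray  # 0 = sooner, 1 = later
    side_of_sooner: np.ndarray | None = None

    def __post_init__(self):
        if self.frame not in ("pain", "relief", "unframed"):
            raise ValueError(f"unknown frame {self.frame!r}")
        n = len(self.choice)
        for name in ("x_sooner", "x_later", "t_sooner", "t_later"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise ValueError(f"{name} length mismatch")
            setattr(self, name, arr)
        self.choice = np.asarray(self.choice, dtype=int)
        if not np.isin(self.choice, (0, 1)).all():
            raise ValueError("choice must be coded 0 (sooner) or 1 (later)")

    def __len__(self) -> int:
        return len(self.choice)

    @classmethod
    def from_pairs(cls, subject_id: str, frame: str, pairs: list[ChoicePair],
                   choices) -> "ChoiceDataset":
        return cls(
            subject_id=subject_id,
            frame=frame,
            x_sooner=np.array([p.sooner.magnitude for p in pairs], dtype=float),
            x_later=np.array([p.later.magnitude for p in pairs], dtype=float),
            t_sooner=np.array([p.sooner.delay for p in pairs], dtype=float),
            t_later=np.array([p.later.delay for p in pairs], dtype=float),
            choice=np.asarray(choices, dtype=int),
            side_of_sooner=np.array([p.side_of_sooner for p in pairs]),
        )

    def pairs(self) -> list[ChoicePair]:
        out = []
        for i in range(len(self)):
            side = (str(self.side_of_sooner[i])
                    if self.side_of_sooner is not None else "left")
            out.append(ChoicePair(
                ChoiceOption(float(self.x_sooner[i]), int(self.t_sooner[i])),
                ChoiceOption(float(self.x_later[i]), int(self.t_later[i])),
                side_of_sooner=side, frame=self.frame))
        return out

    def pooled_with(self, other: "ChoiceDataset") -> "ChoiceDataset":
        """Concatenate two frames of the same subject (frames pooled)."""
        return ChoiceDataset(
            subject_id=self.subject_id,
            frame="unframed",
            x_sooner=np.concatenate([self.x_sooner, other.x_sooner]),
            x_later=np.concatenate([self.x_later, other.x_later]),
            t_sooner=np.concatenate([self.t_sooner, other.t_sooner]),
            t_later=np.concatenate([self.t_later, other.t_later]),
            choice=np.concatenate([self.choice, other.choice]),
        )


def log_choice_probability(dv, beta):
    """log p(choose i) where dv = v_i - v_j, numerically stable."""
    z = np.asarray(beta * np.asarray(dv, dtype=float))
    return -np.logaddexp(0.0, -z)


def choice_probability(v_i, v_j, beta) -> np.ndarray | float:
    """Softmax probability of choosing option i over option j."""
    if np.any(np.asarray(beta) < 0):
        raise ValueError("beta must be non-negative")
    return np.exp(log_choice_probability(np.asarray(v_i) - np.asarray(v_j), beta))


def dataset_loglik(data: ChoiceDataset, spec: ModelSpec, params: ModelParams,
                   wparams: WeibullUtilityParams | None = None) -> float:
    """Summed log-likelihood of the observed choices under one model."""
    if len(data) == 0:
        raise ValueError("empty dataset")
    dv = pair_value_difference(data.x_sooner, data.x_later, data.t_sooner,
                               data.t_later, params, spec, wparams)
    # dv is v_later - v_sooner; flip sign for trials where sooner was chosen
    signed = np.where(data.choice == 1, dv, -dv)
    return float(np.sum(log_choice_probability(signed, params.beta)))


def per_record_probabilities(data: ChoiceDataset, spec: ModelSpec,
                             params: ModelParams,
                             wparams: WeibullUtilityParams | None = None,
                             clip: float = 1e-12) -> pd.DataFrame:
    """Per-record choice probabilities and log-likelihood terms (debugging).

    Probabilities are clipped away from {0, 1} for display only; the
    summed log-likelihood column is exact.
    """
    dv = pair_value_difference(data.x_sooner, data.x_later, data.t_sooner,
                               data.t_later, params, spec, wparams)
    logp_later = log_choice_probability(dv, params.beta)
    logp_sooner = log_choice_probability(-dv, params.beta)
    logp_chosen = np.where(data.choice == 1, logp_later, logp_sooner)
    return pd.DataFrame({
        "s1_magnitude": data.x_sooner, "s2_magnitude": data.x_later,
        "d1": data.t_sooner, "d2": data.t_later, "choice": data.choice,
        "value_diff": np.asarray(dv, dtype=float),
        "p_later": np.clip(np.exp(logp_later), clip, 1 - clip),
        "loglik": logp_chosen,
    })


def write_choice_csv(data: ChoiceDataset, path) -> None:
    df = pairs_to_frame(data.pairs())
    df["choice"] = data.choice
    df.insert(0, "subject_id", data.subject_id)
    df.to_csv(path, index=False)


def read_choice_csv(path) -> list[ChoiceDataset]:
    """Read one or more subject x frame datasets from a choice CSV.

    Expects the columns written by :func:`write_choice_csv`; raises with the
    offending row index on malformed choice codes.
    """
    df = pd.read_csv(path, comment="#")
    required = {"s1_magnitude", "s2_magnitude", "d1", "d2", "choice"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"choice CSV missing columns: {sorted(missing)}")
    bad = df.index[~df["choice"].isin((0, 1))]
    if len(bad):
        raise ValueError(f"invalid choice codes at rows {list(bad[:10])}")
    if "subject_id" not in df.columns:
        df["subject_id"] = "s0"
    if "frame" not in df.columns:
        df["frame"] = "unframed"
    out = []
    for (sid, frame), g in df.groupby(["subject_id", "frame"], sort=True):
        out.append(ChoiceDataset(
            subject_id=str(sid), frame=str(frame),
            x_sooner=g["s1_magnitude"].to_numpy(float),
            x_later=g["s2_magnitude"].to_numpy(float),
            t_sooner=g["d1"].to_numpy(float),
            t_later=g["d2"].to_numpy(float),
            choice=g["choice"].to_numpy(int),
            side_of_sooner=(g["side_of_sooner"].to_numpy()
                            if "side_of_sooner" in g.columns else None),
        ))
    return out
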