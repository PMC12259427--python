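"""NONMEM-style longitudinal dataset container and CSV dialect.

Columns: ID, TIME (h from first dose), AMT (mg, empty for observations),
DUR (h infusion duration), EVID (1 dose / 0 observation), DV (mg/L, empty
for doses), MDV (1 for doses), SEX (0 male / 1 female), CRRT, ECMO (0/1),
AGE (y), WT (kg), HT (cm), ALB (g/L), SCR (umol/L).

Within a subject rows are ordered by time with observations before doses
at equal times — a trough recorded at a scheduled dose time is pre-dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NONMEM_COLUMNS", "Dataset", "SubjectArrays"]

NONMEM_COLUMNS = [
    "ID", "TIME", "AMT", "DUR", "EVID", "DV", "MDV",
    "SEX", "CRRT", "ECMO", "AGE", "WT", "HT", "ALB", "SCR",
]

_COVARIATE_MAP = {
    "sex": "SEX", "crrt": "CRRT", "ecmo": "ECMO", "age": "AGE",
    "weight": "WT", "height": "HT", "albumin": "ALB", "scr": "SCR",
}


@dataclass
class SubjectArrays:
    """Padded per-subject arrays for vectorized likelihood evaluation."""

    ids: np.ndarray          # (n,) subject identifiers
    y: np.ndarray            # (n, m) observed concentrations, 0 where masked
    t_obs: np.ndarray        # (n, m) observation times
    obs_mask: np.ndarray     # (n, m) bool
    dose_start: np.ndarray   # (n, d)
    dose_rate: np.ndarray    # (n, d) mg/h
    dose_dur: np.ndarray     # (n, d)
    dose_mask: np.ndarray    # (n, d) bool
    covariates: pd.DataFrame  # one row per subject, lower-case names

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    @property
    def n_obs(self) -> int:
        return int(self.obs_mask.sum())

    def subset(self, idx) -> "SubjectArrays":
        """Row-select subjects (with repetition) — bootstrap resampling."""
        idx = np.asarray(idx)
        return SubjectArrays(
            ids=np.arange(len(idx)),
            y=self.y[idx],
            t_obs=self.t_obs[idx],
            obs_mask=self.obs_mask[idx],
            dose_start=self.dose_start[idx],
            dose_rate=self.dose_rate[idx],
            dose_dur=self.dose_dur[idx],
            dose_mask=self.dose_mask[idx],
            covariates=self.covariates.iloc[idx].reset_index(drop=True),
        )


class Dataset:
    """A dosing/observation table in the NONMEM-style dialect."""

    def __init__(self, df: pd.DataFrame, check_order: bool = False):
        missing = [c for c in NONMEM_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        unknown = [c for c in df.columns if c not in NONMEM_COLUMNS]
        if unknown:
            raise ValueError(f"unknown columns: {unknown}")
        df = df[NONMEM_COLUMNS].copy()
        self._validate(df, check_order)
        # stable sort: observations precede doses at equal times
        df = df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)
        self.df = df

    @staticmethod
    def _validate(df: pd.DataFrame, check_order: bool) -> None:
        if not df["EVID"].isin([0, 1]).all():
            raise ValueError("EVID must be 0 (observation) or 1 (dose)")
        doses = df["EVID"] == 1
        if df.loc[doses, "AMT"].isna().any() or (df.loc[doses, "AMT"] <= 0).any():
            raise ValueError("dose rows need a positive AMT")
        if df.loc[~doses, "DV"].isna().any():
            raise ValueError("observation rows need a DV")
        if (df.loc[~doses, "DV"] < 0).any():
            raise ValueError("observed concentrations must be >= 0")
        if (df["TIME"] < 0).any():
            raise ValueError("times must be >= 0")
        if check_order:
            for sid, grp in df.groupby("ID", sort=False):
                t = grp["TIME"].to_numpy()
                if np.any(np.diff(t) < 0):
                    raise ValueError(f"non-monotone times within subject {sid}")

    # -- round-trip CSV ----------------------------------------------------
    def write_csv(self, path) -> None:
        # %.17g guarantees binary-lossless float round-trips
        self.df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path) -> "Dataset":
        df = pd.read_csv(path)
        return cls(df, check_order=True)

    def equals(self, other: "Dataset") -> bool:
        a, b = self.df, other.df
        if a.shape != b.shape:
            return False
        for c in NONMEM_COLUMNS:
            x, y = a[c].to_numpy(dtype=float), b[c].to_numpy(dtype=float)
            same = np.isclose(x, y, rtol=0, atol=1e-9) | (np.isnan(x) & np.isnan(y))
            if not same.all():
                return False
        return True

    # -- construction ------------------------------------------------------
    @classmethod
    def from_subjects(cls, subjects) -> "Dataset":
        rows = []
        for s in subjects:
            cov = s.covariates
            base = {
                "SEX": cov.sex, "CRRT": cov.crrt, "ECMO": cov.ecmo,
                "AGE": cov.age, "WT": cov.weight, "HT": cov.height,
                "ALB": cov.albumin, "SCR": cov.scr,
            }
            for d in s.dose_events:
                rows.append({
                    "ID": s.id, "TIME": d.start_time, "AMT": d.amount,
                    "DUR": d.duration, "EVID": 1, "DV": np.nan, "MDV": 1, **base,
                })
            for o in s.observations:
                rows.append({
                    "ID": s.id, "TIME": o.time, "AMT": np.nan, "DUR": np.nan,
                    "EVID": 0, "DV": o.concentration, "MDV": 0, **base,
                })
        return cls(pd.DataFrame(rows, columns=NONMEM_COLUMNS))

    # -- estimation arrays -------------------------------------------------
    def arrays(self) -> SubjectArrays:
        df = self.df
        ids = df["ID"].unique()
        n = len(ids)
        obs = df[df["EVID"] == 0]
        dos = df[df["EVID"] == 1]
        m = int(obs.groupby("ID").size().max()) if len(obs) else 0
        d = int(dos.groupby("ID").size().max()) if len(dos) else 0
        y = np.zeros((n, m))
        t_obs = np.zeros((n, m))
        obs_mask = np.zeros((n, m), dtype=bool)
        dose_start = np.zeros((n, d))
        dose_rate = np.zeros((n, d))
        dose_dur = np.full((n, d), 1.0)
        dose_mask = np.zeros((n, d), dtype=bool)
        cov_rows = []
        for i, sid in enumerate(ids):
            o = obs[obs["ID"] == sid]
            k = len(o)
            y[i, :k] = o["DV"].to_numpy()
            t_obs[i, :k] = o["TIME"].to_numpy()
            obs_mask[i, :k] = True
            dd = dos[dos["ID"] == sid]
            k = len(dd)
            dose_start[i, :k] = dd["TIME"].to_numpy()
            dur = dd["DUR"].fillna(1.0).to_numpy()
            dose_dur[i, :k] = dur
            dose_rate[i, :k] = dd["AMT"].to_numpy() / dur
            dose_mask[i, :k] = True
            first = df[df["ID"] == sid].iloc[0]
            cov_rows.append({lo: first[up] for lo, up in _COVARIATE_MAP.items()})
        return SubjectArrays(
            ids=ids, y=y, t_obs=t_obs, obs_mask=obs_mask,
            dose_start=dose_start, dose_rate=dose_rate, dose_dur=dose_dur,
            dose_mask=dose_mask,
            covariates=pd.DataFrame(cov_rows),
        )

    def __len__(self) -> int:
        return len(self.df)
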