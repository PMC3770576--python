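"""Endophenotype derivations and the pairwise correlation screen.

The panel mirrors the quantitative brain measures used as endophenotypes in
mtDNA association work: normalized regional/whole-brain volumes, cortical
thicknesses and their two-year percent changes, the hippocampal occupancy
score (HOC), and cognitive change scores (ADAS-Cog 11).

Conventions:

* HOC = mean over hemispheres of hipp / (hipp + inferior-lateral-ventricle);
  values near 1 indicate a hippocampus filling its fossa, low values
  degenerative atrophy.
* percent change = 100 * (follow-up - baseline) / baseline, so tissue loss is
  negative.
* change score = follow-up - baseline.
* volume normalization defaults to the ICV-proportion rescaled by a reference
  ICV (typically the sample mean) so values stay on the mm^3 scale.

Missing inputs propagate as NaN; they are never silently filled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_hoc",
    "percent_change",
    "change_score",
    "normalize_volume",
    "correlation_screen",
    "derive_panel",
    "read_subject_table",
    "PhenotypeDerivation",
]

COVARIATE_COLUMNS = ("age", "sex", "apoe4")
DIAGNOSES = ("CN", "MCI", "AD")


def compute_hoc(hipp_left, hipp_right, ilv_left, ilv_right):
    """Hippocampal occupancy: per-hemisphere ratio, averaged.

    HOC_h = hipp_h / (hipp_h + ilv_h); returns (HOC_L + HOC_R) / 2, in [0, 1].
    Accepts scalars or aligned arrays; a zero denominator in either
    hemisphere raises.
    """
    hl, hr = np.asarray(hipp_left, float), np.asarray(hipp_right, float)
    il, ir = np.asarray(ilv_left, float), np.asarray(ilv_right, float)
    for name, arr in (("hipp_left", hl), ("hipp_right", hr), ("ilv_left", il), ("ilv_right", ir)):
        if np.any(arr < 0):
            raise ValueError(f"{name} contains negative volumes")
    dl, dr = hl + il, hr + ir
    if np.any(dl == 0) or np.any(dr == 0):
        raise ValueError("zero hippocampus+ventricle denominator in a hemisphere")
    out = 0.5 * (hl / dl + hr / dr)
    return float(out) if out.ndim == 0 else out


def percent_change(baseline, followup):
    """Two-year percent change: 100 * (followup - baseline) / baseline.

    Losses are negative.  NaN inputs propagate; a zero baseline raises.
    """
    b = np.asarray(baseline, float)
    f = np.asarray(followup, float)
    if np.any(b == 0):
        raise ValueError("zero baseline in percent_change")
    out = 100.0 * (f - b) / b
    return float(out) if out.ndim == 0 else out


def change_score(baseline, followup):
    """Plain difference followup - baseline; missing values propagate as NaN."""
    b = np.asarray(baseline, float)
    f = np.asarray(followup, float)
    out = f - b
    return float(out) if out.ndim == 0 else out


def normalize_volume(volume, icv, method: str = "proportion_rescaled",
                     reference_icv: float | None = None):
    """Normalize a volume by total intracranial volume (ICV).

    ``proportion``: volume / ICV (dimensionless).
    ``proportion_rescaled``: (volume / ICV) * reference_icv, staying in mm^3;
    ``reference_icv`` is typically the sample-mean ICV.
    ``none``: passthrough.
    """
    v = np.asarray(volume, float)
    i = np.asarray(icv, float)
    if method == "none":
        return float(v) if v.ndim == 0 else v
    if np.any(i <= 0):
        raise ValueError("ICV must be positive")
    if method == "proportion":
        out = v / i
    elif method == "proportion_rescaled":
        if reference_icv is None:
            raise ValueError("proportion_rescaled requires reference_icv")
        out = v / i * reference_icv
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return float(out) if out.ndim == 0 else out


def correlation_screen(
    panel: pd.DataFrame, min_pairs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations over pairwise-complete observations.

    Returns (r, p) DataFrames, symmetric with unit/zero diagonals.  Cells
    with fewer than ``min_pairs`` complete pairs are NaN.
    """
    cols = list(panel.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            sub = panel[[a, b]].dropna()
            if len(sub) < min_pairs:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            res = stats.pearsonr(sub[a], sub[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p


# ---------------------------------------------------------------------------
# panel derivation
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeDerivation:
    """A named endophenotype computed from subject-table columns."""

    name: str
    inputs: tuple[str, ...]
    func: Callable[..., np.ndarray]
    provenance: str = ""


def _hoc_derivation(name: str, suffix: str = "") -> PhenotypeDerivation:
    cols = tuple(c + suffix for c in ("hipp_left", "hipp_right", "ilv_left", "ilv_right"))
    return PhenotypeDerivation(
        name=name,
        inputs=cols,
        func=lambda hl, hr, il, ir: compute_hoc(hl, hr, il, ir),
        provenance="mean hemisphere hipp/(hipp+ilv)",
    )


def standard_derivations(reference_icv: float | None = None) -> list[PhenotypeDerivation]:
    """The default endophenotype panel derivable from a subject table.

    Covers the families tested in mtDNA endophenotype scans: normalized
    volumes, baseline thicknesses, two-year percent changes, HOC at baseline
    and its change, and ADAS-Cog baseline and change.
    Only derivations whose input columns exist are applied.
    """
    der: list[PhenotypeDerivation] = [
        _hoc_derivation("hoc_baseline"),
        _hoc_derivation("hoc_m24", suffix="_m24"),
        PhenotypeDerivation(
            "hoc_pct_change",
            ("hipp_left", "hipp_right", "ilv_left", "ilv_right",
             "hipp_left_m24", "hipp_right_m24", "ilv_left_m24", "ilv_right_m24"),
            lambda hl, hr, il, ir, hl2, hr2, il2, ir2: percent_change(
                compute_hoc(hl, hr, il, ir), compute_hoc(hl2, hr2, il2, ir2)
            ),
            provenance="percent change of HOC over two years",
        ),
        PhenotypeDerivation(
            "adas_cog_baseline", ("adas_cog",), lambda a: np.asarray(a, float),
            provenance="ADAS-Cog 11 total at baseline",
        ),
        PhenotypeDerivation(
            "adas_cog_change", ("adas_cog", "adas_cog_m24"),
            lambda b, f: change_score(b, f),
            provenance="ADAS-Cog 11 two-year change",
        ),
    ]
    for roi in ("entorhinal", "parahippocampal", "temporal_pole"):
        der.append(
            PhenotypeDerivation(
                f"{roi}_thickness_baseline", (f"{roi}_thickness",),
                lambda x: np.asarray(x, float),
                provenance="baseline cortical thickness (mm)",
            )
        )
        der.append(
            PhenotypeDerivation(
                f"{roi}_thickness_pct_change",
                (f"{roi}_thickness", f"{roi}_thickness_m24"),
                lambda b, f: percent_change(b, f),
                provenance="two-year percent change of cortical thickness",
            )
        )
    for vol in ("whole_brain", "hipp_left", "hipp_right"):
        der.append(
            PhenotypeDerivation(
                f"{vol}_volume_norm", (vol if vol == "whole_brain" else vol, "icv"),
                lambda v, icv: normalize_volume(
                    v, icv, "proportion_rescaled", reference_icv
                )
                if reference_icv
                else normalize_volume(v, icv, "proportion"),
                provenance="ICV-normalized volume",
            )
        )
        der.append(
            PhenotypeDerivation(
                f"{vol}_atrophy_pct",
                (vol, f"{vol}_m24"),
                lambda b, f: percent_change(b, f),
                provenance="two-year percent change of volume",
            )
        )
    return der


def derive_panel(
    subjects: pd.DataFrame,
    derivations: Sequence[PhenotypeDerivation] | None = None,
) -> pd.DataFrame:
    """Apply derivations to a subject table, returning the phenotype panel.

    The panel is indexed like ``subjects``; derivations whose inputs are
    absent are skipped.  NaNs in the inputs propagate into the panel.
    """
    if derivations is None:
        ref = float(subjects["icv"].mean()) if "icv" in subjects else None
        derivations = standard_derivations(reference_icv=ref)
    panel = pd.DataFrame(index=subjects.index)
    for d in derivations:
        if not all(c in subjects.columns for c in d.inputs):
            continue
        args = [subjects[c].to_numpy(float) for c in d.inputs]
        try:
            panel[d.name] = d.func(*args)
        except ValueError:
            # row-wise fallback so one bad row does not kill the column
            vals = np.full(len(subjects), np.nan)
            for k in range(len(subjects)):
                try:
                    vals[k] = d.func(*[a[k] for a in args])
                except ValueError:
                    pass
            panel[d.name] = vals
    return panel


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited subject table keyed by ``individual_id``.

    Requires ``individual_id``, ``age``, ``sex`` and ``apoe4`` columns; all
    other columns are carried as measures.  ``sex`` is normalized to
    'male'/'female'.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"individual_id", "age", "sex", "apoe4"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"subject table {path} lacks columns {sorted(missing)}")
    if df["individual_id"].duplicated().any():
        raise ValueError(f"subject table {path}: duplicate individual ids")
    if (df["age"] <= 0).any():
        raise ValueError("ages must be positive")
    sex = df["sex"].astype(str).str.lower().map(
        {"m": "male", "male": "male", "1": "male", "f": "female", "female": "female", "0": "female"}
    )
    if sex.isna().any():
        raise ValueError("sex column contains unrecognized codes")
    df["sex"] = sex
    return df.set_index("individual_id", drop=False)
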