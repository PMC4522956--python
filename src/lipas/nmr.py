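"""Chemical-shift perturbation (CSP) analysis of ¹⁵N-HSQC peak lists.

Given assigned free- and bound-state peak lists, the combined amide
perturbation per residue is the standard quadrature form

    Δδ(¹⁵N+¹H) = sqrt( (Δδ¹⁵N / 10)² + (Δδ¹H)² )   [ppm]

(the nitrogen axis scaled by 1/10 for its wider dispersion), and peak
intensity changes are reported as (I − I₀)/I₀ relative to the free
spectrum. Matching is by residue id only — assignments are taken as
given; residues present in just one list are reported separately as
candidates for exchange broadening.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

PEAK_COLUMNS = ["residue_id", "delta_15N_ppm", "delta_1H_ppm", "intensity"]


class PeakList:
    """Assigned ¹⁵N-HSQC peak list (one row per residue)."""

    def __init__(self, table: pd.DataFrame):
        missing = set(PEAK_COLUMNS) - set(table.columns)
        if missing:
            raise ValidationError(f"peak list lacks columns {sorted(missing)}")
        t = table[PEAK_COLUMNS].copy()
        if t["residue_id"].duplicated().any():
            dup = t.loc[t["residue_id"].duplicated(), "residue_id"].tolist()
            raise ValidationError(f"duplicate residue ids {dup}")
        if not np.isfinite(t[["delta_15N_ppm", "delta_1H_ppm"]].to_numpy()).all():
            raise ValidationError("non-finite chemical shifts")
        if (t["intensity"] < 0).any():
            raise ValidationError("negative intensities")
        self.table = t.set_index("residue_id", drop=False)

    def __len__(self):
        return len(self.table)

    @property
    def residue_ids(self):
        return self.table["residue_id"].tolist()

    @classmethod
    def from_tsv(cls, path) -> "PeakList":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def chemical_shift_perturbation(free: PeakList, bound: PeakList) -> pd.DataFrame:
    """Combined CSP per residue common to both lists.

    Returns a DataFrame with columns ``residue_id``, ``dd15n``, ``dd1h``,
    ``csp`` (all ppm) carrying attrs ``only_free`` / ``only_bound`` with
    the unmatched residue ids.
    """
    common = sorted(set(free.residue_ids) & set(bound.residue_ids))
    if not common:
        raise ValidationError("no residue ids common to both peak lists")
    f = free.table.loc[common]
    b = bound.table.loc[common]
    dd15n = (b["delta_15N_ppm"] - f["delta_15N_ppm"]).to_numpy()
    dd1h = (b["delta_1H_ppm"] - f["delta_1H_ppm"]).to_numpy()
    csp = np.sqrt((dd15n / 10.0) ** 2 + dd1h**2)
    out = pd.DataFrame(
        {"residue_id": common, "dd15n": dd15n, "dd1h": dd1h, "csp": csp}
    )
    out.attrs["only_free"] = sorted(set(free.residue_ids) - set(common))
    out.attrs["only_bound"] = sorted(set(bound.residue_ids) - set(common))
    return out


def relative_intensity_change(free: PeakList, bound: PeakList) -> pd.DataFrame:
    """(I − I₀)/I₀ per common residue; I₀ = 0 rows flagged, not divided."""
    common = sorted(set(free.residue_ids) & set(bound.residue_ids))
    if not common:
        raise ValidationError("no residue ids common to both peak lists")
    i0 = free.table.loc[common, "intensity"].to_numpy(dtype=float)
    i1 = bound.table.loc[common, "intensity"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(i0 > 0, (i1 - i0) / np.where(i0 > 0, i0, 1.0), np.nan)
    return pd.DataFrame(
        {
            "residue_id": common,
            "intensity_free": i0,
            "intensity_bound": i1,
            "rel_intensity_change": rel,
            "reference_zero": i0 == 0,
        }
    )


def perturbation_table(free: PeakList, bound: PeakList) -> pd.DataFrame:
    """CSP and intensity changes merged into one per-residue table."""
    csp = chemical_shift_perturbation(free, bound)
    inten = relative_intensity_change(free, bound)
    out = csp.merge(
        inten[["residue_id", "rel_intensity_change", "reference_zero"]],
        on="residue_id",
    )
    out.attrs.update(csp.attrs)
    return out


def rank_perturbed(table: pd.DataFrame, threshold: float | str = "mean+1sd") -> pd.DataFrame:
    """Sort residues by combined CSP (descending) and flag significance.

    ``threshold`` is either a number in ppm or the default rule
    ``"mean+1sd"`` (mean + 1 standard deviation of the combined CSP).
    """
    if table.empty:
        raise ValidationError("empty perturbation table")
    csp = table["csp"].to_numpy(dtype=float)
    if threshold == "mean+1sd":
        cut = float(csp.mean() + csp.std(ddof=0))
    else:
        cut = float(threshold)
    out = table.sort_values("csp", ascending=False, kind="mergesort").copy()
    # an all-zero table has cut 0; nothing exceeds it strictly
    out["significant"] = out["csp"].to_numpy() > cut if cut > 0 else out["csp"].to_numpy() > 0
    out.attrs["threshold_ppm"] = cut
    return out.reset_index(drop=True)
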