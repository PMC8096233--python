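"""Amide chemical-shift and 15N relaxation analysis of H3 tail peak tables.

Works on residue-keyed amide peak lists (1H/15N positions in ppm plus peak
heights) rather than raw spectra.  Provides:

* combined chemical-shift differences, Δδ = sqrt(ΔδH² + (0.154·ΔδN)²)
* classification of the hexasome's doubled peaks into nucleosome-like
  (hex-N) and tetrasome-like (hex-T) subsets by shift overlap with the
  reference species
* hex-T / hex-N peak-height asymmetry (a proxy for differential tail
  dynamics at matched overall tumbling)
* T1/T2 single-exponential fits (no offset) with covariance errors,
  heteronuclear NOE from saturated/reference height pairs, and T1/T2 ratios
  with first-order error propagation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import FitError, InputError

#: 15N scaling weight in the combined amide shift difference
N_WEIGHT = 0.154

#: classification ambiguity threshold (ppm) on |Δδ_N - Δδ_T|
AMBIGUITY_PPM = 0.005

# relaxation delay schedules (ms); duplicates are independent measurements
T1_DELAYS_MS = [10, 10, 100, 100, 200, 200, 500, 500, 1000, 1000, 2000, 2000]
T2_DELAYS_MS = [16.96, 16.96, 50.88, 50.88, 67.84, 67.84, 101.76, 101.76,
                152.64, 152.64, 203.52, 203.52]

PEAK_COLUMNS = ["residue", "dH_ppm", "dN_ppm", "height"]


@dataclass
class PeakList:
    """Residue-keyed amide peak table for one species.

    ``data`` columns: residue (int), dH_ppm, dN_ppm, height, and optionally
    ``subset`` (hex-N / hex-T), ``overlap`` (bool) and ``ambiguous`` (bool).
    """

    species: str
    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in PEAK_COLUMNS if c not in self.data.columns]
        if missing:
            raise InputError(f"peak list missing columns: {missing}")
        if not np.isfinite(self.data[["dH_ppm", "dN_ppm"]].to_numpy()).all():
            raise InputError("chemical shifts must be finite")
        if "subset" in self.data.columns:
            labeled = self.data[self.data["subset"].notna()]
            if labeled.duplicated(subset=["residue", "subset"]).any():
                raise InputError("duplicate residue entries within a subset")
        # unlabeled lists may carry doubled peaks (one per tail state)
        if (self.data.groupby("residue").size() > 2).any():
            raise InputError("more than two peaks for a residue")

    @property
    def residues(self) -> np.ndarray:
        return self.data["residue"].to_numpy()

    def subset(self, label: str) -> pd.DataFrame:
        if "subset" not in self.data.columns:
            raise InputError("peak list carries no subset labels")
        return self.data[self.data["subset"] == label]


@dataclass
class CSDProfile:
    """Per-residue combined amide shift differences between two species."""

    species_a: str
    species_b: str
    data: pd.DataFrame            # residue, d_dh, d_dn, csd, overlap
    unmatched_a: list = field(default_factory=list)
    unmatched_b: list = field(default_factory=list)

    @property
    def mean_csd(self) -> float:
        """Mean Δδ over matched residues, excluding overlap-flagged ones."""
        d = self.data
        if "overlap" in d.columns:
            d = d[~d["overlap"].astype(bool)]
        return float(d["csd"].mean())


def csd(d_dh, d_dn) -> np.ndarray:
    """Combined amide shift difference from 1H and 15N components (ppm)."""
    d_dh = np.asarray(d_dh, dtype=float)
    d_dn = np.asarray(d_dn, dtype=float)
    return np.sqrt(d_dh ** 2 + (N_WEIGHT * d_dn) ** 2)


def chemical_shift_difference(a: PeakList, b: PeakList) -> CSDProfile:
    """Per-residue Δδ between two peak lists, matched by residue number.

    Unmatched residues are reported on the profile, never silently dropped.
    A residue is overlap-flagged in the output if flagged in either input.
    """
    da, db = a.data, b.data
    merged = da.merge(db, on="residue", suffixes=("_a", "_b"))
    if merged.empty:
        raise InputError(f"no matched residues between {a.species!r} and {b.species!r}")
    d_dh = merged["dH_ppm_a"] - merged["dH_ppm_b"]
    d_dn = merged["dN_ppm_a"] - merged["dN_ppm_b"]
    out = pd.DataFrame({
        "residue": merged["residue"],
        "d_dh": d_dh,
        "d_dn": d_dn,
        "csd": csd(d_dh, d_dn),
    })
    overlap = np.zeros(len(merged), dtype=bool)
    for side in ("_a", "_b"):
        col = "overlap" + side
        if col in merged.columns:
            overlap |= merged[col].fillna(False).astype(bool).to_numpy()
    out["overlap"] = overlap
    return CSDProfile(
        species_a=a.species, species_b=b.species, data=out,
        unmatched_a=sorted(set(da["residue"]) - set(merged["residue"])),
        unmatched_b=sorted(set(db["residue"]) - set(merged["residue"])),
    )


# ---------------------------------------------------------------------------
# hexasome peak classification


def classify_hexasome_peaks(
    hexa: PeakList, nuc: PeakList, tet: PeakList,
    ambiguity_ppm: float = AMBIGUITY_PPM,
) -> PeakList:
    """Label hexasome peaks hex-N or hex-T by shift overlap with references.

    For residues with two hexasome peaks the joint assignment minimizing the
    total Δδ of (peak->nucleosome) + (peak->tetrasome) is chosen, so each
    label is used at most once per residue.  Single peaks take the nearer
    reference.  Ties (|Δδ_N - Δδ_T| < ambiguity_ppm) go to hex-N and are
    flagged ``ambiguous``.
    """
    nuc_pos = nuc.data.set_index("residue")[["dH_ppm", "dN_ppm"]]
    tet_pos = tet.data.set_index("residue")[["dH_ppm", "dN_ppm"]]

    rows = []
    for res, grp in hexa.data.groupby("residue"):
        if len(grp) > 2:
            raise InputError(f"residue {res}: more than two hexasome peaks")
        if res not in nuc_pos.index or res not in tet_pos.index:
            # no reference for this residue; keep peaks unlabeled
            for _, r in grp.iterrows():
                rows.append({**r.to_dict(), "subset": None, "ambiguous": False})
            continue
        dn = nuc_pos.loc[res]
        dt = tet_pos.loc[res]

        def dist(row, ref):
            return float(csd(row["dH_ppm"] - ref["dH_ppm"],
                             row["dN_ppm"] - ref["dN_ppm"]))

        if len(grp) == 1:
            r = grp.iloc[0]
            d_n, d_t = dist(r, dn), dist(r, dt)
            ambiguous = abs(d_n - d_t) < ambiguity_ppm
            label = "hex-N" if (d_n < d_t or ambiguous) else "hex-T"
            rows.append({**r.to_dict(), "subset": label, "ambiguous": ambiguous})
        else:
            p1, p2 = grp.iloc[0], grp.iloc[1]
            # two joint assignments: (p1->N, p2->T) or (p1->T, p2->N)
            cost_a = dist(p1, dn) + dist(p2, dt)
            cost_b = dist(p1, dt) + dist(p2, dn)
            ambiguous = abs(cost_a - cost_b) < ambiguity_ppm
            if cost_a <= cost_b:
                lab1, lab2 = "hex-N", "hex-T"
            else:
                lab1, lab2 = "hex-T", "hex-N"
            rows.append({**p1.to_dict(), "subset": lab1, "ambiguous": ambiguous})
            rows.append({**p2.to_dict(), "subset": lab2, "ambiguous": ambiguous})
    data = pd.DataFrame(rows).reset_index(drop=True)
    return PeakList(species=hexa.species, data=data)


@dataclass
class AsymmetryResult:
    per_residue: pd.DataFrame     # residue, ratio
    mean: float
    sd: float
    skipped: list                 # residues missing either peak or overlapped


def intensity_asymmetry(labeled: PeakList, residue_window: Iterable[int]) -> AsymmetryResult:
    """Window mean of per-residue hex-T / hex-N peak-height ratios.

    Overlap-flagged residues are excluded; residues missing either peak are
    skipped and reported.
    """
    window = set(int(r) for r in residue_window)
    if not window:
        raise InputError("empty residue window")
    d = labeled.data
    if "subset" not in d.columns:
        raise InputError("peak list is not classified (no subset labels)")
    skipped = []
    ratios = []
    for res in sorted(window):
        grp = d[d["residue"] == res]
        if "overlap" in grp.columns and grp["overlap"].fillna(False).astype(bool).any():
            skipped.append(res)
            continue
        hn = grp[grp["subset"] == "hex-N"]["height"]
        ht = grp[grp["subset"] == "hex-T"]["height"]
        if hn.empty or ht.empty or float(hn.iloc[0]) <= 0:
            skipped.append(res)
            continue
        ratios.append({"residue": res, "ratio": float(ht.iloc[0]) / float(hn.iloc[0])})
    if not ratios:
        raise InputError("no usable residues in window after exclusions")
    per = pd.DataFrame(ratios)
    return AsymmetryResult(
        per_residue=per,
        mean=float(per["ratio"].mean()),
        sd=float(per["ratio"].std(ddof=1)) if len(per) > 1 else 0.0,
        skipped=skipped,
    )


# ---------------------------------------------------------------------------
# 15N relaxation


def fit_relaxation_time(series: pd.DataFrame, experiment: str = "T") -> pd.DataFrame:
    """Per-residue single-exponential fits H(d) = H0 * exp(-d/T), no offset.

    ``series`` columns: residue, delay_ms, height (duplicate delays are
    independent observations).  Returns per residue: T_ms with covariance
    error, rate R = 1/T in s^-1 with first-order propagated error, H0, and
    an ``at_bound`` flag for degenerate fits.
    """
    for col in ("residue", "delay_ms", "height"):
        if col not in series.columns:
            raise InputError(f"relaxation series missing column {col!r}")
    if (series["delay_ms"] < 0).any():
        raise InputError("relaxation delays must be non-negative")

    def model(d, h0, t_ms):
        return h0 * np.exp(-d / t_ms)

    rows = []
    for res, grp in series.groupby("residue"):
        d = grp["delay_ms"].to_numpy(dtype=float)
        h = grp["height"].to_numpy(dtype=float)
        if np.unique(d).size < 3:
            raise InputError(f"residue {res}: need >=3 distinct delays")
        h0_0 = float(h[np.argmin(d)])
        pos = h > 0
        if pos.sum() >= 2 and h0_0 > 0:
            slope = np.polyfit(d[pos], np.log(h[pos]), 1)[0]
            t0 = -1.0 / slope if slope < 0 else float(d.max())
        else:
            t0 = float(d.max())
        t0 = float(np.clip(t0, 1e-3, 1e7))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=optimize.OptimizeWarning)
                popt, pcov = optimize.curve_fit(
                    model, d, h, p0=[max(h0_0, 1e-6), t0],
                    bounds=([0.0, 1e-6], [np.inf, np.inf]), maxfev=20000,
                )
        except RuntimeError as exc:
            raise FitError(f"relaxation fit failed for residue {res}: {exc}")
        h0, t_ms = popt
        t_err = float(np.sqrt(max(pcov[1, 1], 0.0)))
        r = 1000.0 / t_ms                      # s^-1
        r_err = r * t_err / t_ms
        rows.append({
            "residue": res, "experiment": experiment,
            "H0": float(h0), "T_ms": float(t_ms), "T_err_ms": t_err,
            "R_s": float(r), "R_err_s": float(r_err),
            "at_bound": bool(t_ms <= 2e-6),
        })
    return pd.DataFrame(rows).sort_values("residue").reset_index(drop=True)


def het_noe(
    saturated: PeakList, reference: PeakList,
    sigma_sat: float = 0.0, sigma_ref: float = 0.0,
) -> pd.DataFrame:
    """Steady-state heteronuclear NOE = H_sat / H_ref per matched residue.

    ``sigma_sat`` / ``sigma_ref`` are single per-spectrum noise estimates;
    the NOE error is |NOE|*sqrt((σ_sat/H_sat)² + (σ_ref/H_ref)²).  Residues
    with non-positive reference height are flagged undefined.
    """
    m = saturated.data.merge(reference.data, on="residue", suffixes=("_sat", "_ref"))
    if m.empty:
        raise InputError("no matched residues between saturated and reference lists")
    rows = []
    for _, r in m.iterrows():
        h_sat, h_ref = float(r["height_sat"]), float(r["height_ref"])
        if h_ref <= 0:
            rows.append({"residue": r["residue"], "noe": np.nan, "noe_err": np.nan,
                         "undefined": True})
            continue
        noe = h_sat / h_ref
        if sigma_sat or sigma_ref:
            rel_sat = (sigma_sat / h_sat) ** 2 if h_sat != 0 else np.inf
            err = abs(noe) * np.sqrt(rel_sat + (sigma_ref / h_ref) ** 2)
        else:
            err = 0.0
        rows.append({"residue": r["residue"], "noe": noe, "noe_err": err,
                     "undefined": False})
    return pd.DataFrame(rows).sort_values("residue").reset_index(drop=True)


def t1_t2_ratio(t1: pd.DataFrame, t2: pd.DataFrame) -> pd.DataFrame:
    """Per-residue T1/T2 with first-order propagated error.

    Residues missing from either fit table are skipped and listed in the
    frame's ``attrs["skipped"]``.  Overlap/at_bound flags are carried through.
    """
    m = t1.merge(t2, on="residue", suffixes=("_1", "_2"))
    skipped = sorted(
        set(t1["residue"]).symmetric_difference(set(t2["residue"]))
    )
    if m.empty:
        raise InputError("no residues common to the T1 and T2 fits")
    ratio = m["T_ms_1"] / m["T_ms_2"]
    err = ratio * np.sqrt(
        (m["T_err_ms_1"] / m["T_ms_1"]) ** 2 + (m["T_err_ms_2"] / m["T_ms_2"]) ** 2
    )
    out = pd.DataFrame({
        "residue": m["residue"],
        "t1_t2": ratio,
        "t1_t2_err": err,
        "at_bound": m.get("at_bound_1", False) | m.get("at_bound_2", False),
    })
    for flag in ("overlap_1", "overlap_2"):
        if flag in m.columns:
            out["overlap"] = out.get("overlap", False) | m[flag].astype(bool)
    out.attrs["skipped"] = skipped
    return out.sort_values("residue").reset_index(drop=True)
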