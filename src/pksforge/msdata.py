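"""Centroided LC-MS runs: EIC extraction and chlorine-tag scoring.

A run is an ordered list of scans, each a centroided peak list.  Target
compounds are detected by extracting an ion chromatogram (EIC) at the
predicted adduct m/z and scoring the chlorine isotope tag: enzymatic
chlorination leaves an M/M+2 doublet spaced by 1.99705 Da with abundance
ratio ≈ 0.32 per chlorine, which cleanly separates engineered chlorinated
products from the unchlorinated background of a culture extract.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .masscalc import (
    ADDUCTS,
    CL_M2_RATIO,
    CL_SPACING,
    adduct_mz,
    isotope_pattern,
    parse_formula,
)

__all__ = [
    "MSRun",
    "Chromatogram",
    "ChlorinationScore",
    "read_peaklist_csv",
    "write_peaklist_csv",
    "read_mzml",
    "extract_eic",
    "score_chlorination",
    "screen_features",
    "write_feature_report",
]


@dataclass
class MSRun:
    """Ordered scans: (time in minutes, (mz, intensity) peak arrays)."""

    times: np.ndarray  # (n_scans,), nondecreasing
    peaks: list[np.ndarray]  # each (n_peaks, 2): mz, intensity

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) < 0):
            raise ValueError("scan times must be nondecreasing")
        if len(self.peaks) != len(self.times):
            raise ValueError("one peak list per scan required")
        for p in self.peaks:
            if p.size and np.any(p[:, 1] < 0):
                raise ValueError("negative peak intensity")

    @property
    def n_scans(self) -> int:
        return len(self.times)


@dataclass
class Chromatogram:
    """(time, intensity) series for one m/z window."""

    times: np.ndarray
    intensities: np.ndarray

    @property
    def apex_time(self) -> float:
        return float(self.times[int(np.argmax(self.intensities))])

    @property
    def apex_intensity(self) -> float:
        return float(self.intensities.max())


@dataclass
class ChlorinationScore:
    """Chlorine-tag evidence at one m/z.

    ``score`` compares the observed (M+2)/M ratio to the single-Cl
    expectation via a Gaussian kernel; ``n_cl_best`` is the 0–3 Cl
    hypothesis nearest the observation.
    """

    observed_ratio: float
    expected_ratio: float
    score: float
    n_cl_best: int
    found: bool = True


def read_peaklist_csv(path: str | Path) -> MSRun:
    """Read the canonical peak-list CSV (scan_time_min, mz, intensity)."""
    df = pd.read_csv(path)
    required = {"scan_time_min", "mz", "intensity"}
    if not required <= set(df.columns):
        raise ValueError(f"peak list must have columns {sorted(required)}")
    times = []
    peaks = []
    for t, grp in df.groupby("scan_time_min", sort=True):
        times.append(float(t))
        peaks.append(grp[["mz", "intensity"]].to_numpy(dtype=float))
    return MSRun(times=np.array(times), peaks=peaks)


def write_peaklist_csv(run: MSRun, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["scan_time_min", "mz", "intensity"])
        for t, pk in zip(run.times, run.peaks):
            for mz, inten in pk:
                wr.writerow([f"{t:.5f}", f"{mz:.6f}", f"{inten:.3f}"])


def read_mzml(path: str | Path) -> MSRun:
    """Optional mzML reader (centroided spectra), via pyteomics when present."""
    try:
        from pyteomics import mzml as _mzml
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("mzML support requires pyteomics") from exc
    times, peaks = [], []
    with _mzml.read(str(path)) as reader:
        for spec in reader:
            if spec.get("ms level", 1) != 1:
                continue
            t = spec["scanList"]["scan"][0]["scan start time"]
            times.append(float(t))
            peaks.append(np.column_stack([spec["m/z array"], spec["intensity array"]]))
    order = np.argsort(times)
    return MSRun(times=np.array(times)[order], peaks=[peaks[i] for i in order])


def extract_eic(run: MSRun, mz: float, mz_tol: float = 0.005) -> Chromatogram:
    """Summed intensity within ±mz_tol per scan."""
    if mz_tol <= 0:
        raise ValueError("mz_tol must be > 0")
    intensities = np.zeros(run.n_scans)
    for i, pk in enumerate(run.peaks):
        if pk.size == 0:
            continue
        sel = np.abs(pk[:, 0] - mz) <= mz_tol
        if sel.any():
            intensities[i] = pk[sel, 1].sum()
    return Chromatogram(times=run.times.copy(), intensities=intensities)


def score_chlorination(
    run: MSRun,
    mz0: float,
    mz_tol: float = 0.005,
    rt_window: float = 0.5,
    sigma: float = 0.1,
    rt: float | None = None,
    formula: dict[str, int] | str | None = None,
) -> ChlorinationScore:
    """Score the chlorine isotope tag of the feature at ``mz0``.

    The feature's apex is located from its EIC (or taken at ``rt`` when
    given); intensities at mz0 and the M+2 partner at mz0 + 1.99705 are
    summed over scans within ``rt_window`` minutes of the apex.  When the
    candidate ``formula`` is known, the M+2 contribution of its
    non-chlorine atoms (13C pairs, 18O, 34S, ...) is predicted from the
    isotope envelope and subtracted, so the residual excess isolates the
    chlorine doublet.  The score is
    ``exp(-(excess - expected)^2 / (2 sigma^2))`` against the single-Cl
    expectation; ``n_cl_best`` minimizes the residual over the 0–3 Cl
    hypotheses (expected ratio n * 0.32).
    """
    base = extract_eic(run, mz0, mz_tol)
    if base.apex_intensity <= 0:
        return ChlorinationScore(
            observed_ratio=0.0,
            expected_ratio=CL_M2_RATIO,
            score=0.0,
            n_cl_best=0,
            found=False,
        )
    apex = base.apex_time if rt is None else rt
    sel = np.abs(run.times - apex) <= rt_window
    partner = extract_eic(run, mz0 + CL_SPACING, mz_tol)
    i_m = base.intensities[sel].sum()
    i_m2 = partner.intensities[sel].sum()
    observed = i_m2 / i_m if i_m > 0 else 0.0
    baseline = 0.0
    if formula is not None:
        f = dict(parse_formula(formula) if isinstance(formula, str) else formula)
        f.pop("Cl", None)
        if f:
            # Non-Cl M+2 centroid sits ~2.004 Da up; generous match tolerance.
            baseline = isotope_pattern(f, threshold=1e-6).ratio(2.004, tol=0.05)
    excess = observed - baseline
    hypotheses = [n * CL_M2_RATIO for n in range(4)]
    n_best = int(np.argmin([abs(excess - h) for h in hypotheses]))
    score = float(np.exp(-((excess - CL_M2_RATIO) ** 2) / (2.0 * sigma**2)))
    return ChlorinationScore(
        observed_ratio=observed,
        expected_ratio=CL_M2_RATIO,
        score=score,
        n_cl_best=n_best,
    )


def screen_features(
    run: MSRun,
    targets: list[tuple[str, dict[str, int] | str]],
    adducts: list[str] | None = None,
    mz_tol: float = 0.005,
    rt_window: float = 0.5,
    sigma: float = 0.1,
    score_cutoff: float = 0.8,
) -> pd.DataFrame:
    """Screen a run for predicted products across all configured adducts.

    ``targets`` are (name, formula) pairs.  Each target x adduct row
    reports expected m/z, apex RT, apex intensity, the observed M+2/M
    ratio, the chlorine-tag score, the best Cl-count hypothesis and a
    ``chlorinated`` flag (score >= cutoff and n_cl_best >= 1).
    """
    if adducts is None:
        adducts = list(ADDUCTS)
    rows = []
    for name, formula in targets:
        for add in adducts:
            mz = adduct_mz(formula, add)
            eic = extract_eic(run, mz, mz_tol)
            sc = score_chlorination(
                run, mz, mz_tol=mz_tol, rt_window=rt_window, sigma=sigma,
                formula=formula,
            )
            rows.append(
                {
                    "target": name,
                    "adduct": add,
                    "mz": mz,
                    "apex_rt": eic.apex_time if sc.found else np.nan,
                    "apex_intensity": eic.apex_intensity,
                    "observed_m2_ratio": sc.observed_ratio,
                    "cl_score": sc.score,
                    "n_cl_best": sc.n_cl_best,
                    "found": sc.found,
                    "chlorinated": bool(
                        sc.found and sc.score >= score_cutoff and sc.n_cl_best >= 1
                    ),
                }
            )
    return pd.DataFrame(rows)


def write_feature_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.6g")
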