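"""Benchmark score curves for sidechain RMSF and hydrophobic SASA.

For each category — (amino acid, exposure class) for sidechain RMSF,
amino acid alone for hydrophobic SASA — the distribution of the property
over a reference ensemble collection is estimated with a Gaussian kernel
density (Silverman's rule-of-thumb bandwidth), scaled so its maximum is
1, and then forced monotone non-increasing by a suffix-maximum envelope:
every grid value becomes the maximum of itself and everything to its
right.  Lowering the property value therefore never lowers the score.

Curves are serialized as plain CSV (category, x, y) and are the
compatibility surface for externally generated references.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import AA_3TO1, StructureEnsemble
from .exposure import SasaAnalysis
from .flexibility import (
    ExposureClass,
    load_reference_sasa,
    residue_exposure_classes,
    sidechain_rmsf,
)

__all__ = [
    "BenchmarkCurve",
    "BenchmarkCurveSet",
    "collect_samples",
    "fit_curve",
    "build_benchmark",
    "save_curves",
    "load_curves",
    "GRID_POINTS",
]

logger = logging.getLogger(__name__)

GRID_POINTS = 512
GRID_PADDING_BANDWIDTHS = 3.0


def _category_key(category) -> str:
    if isinstance(category, tuple):
        return ":".join(str(c) for c in category)
    return str(category)


@dataclass
class BenchmarkCurve:
    """Monotone non-increasing score curve for one category."""

    category: str
    x: np.ndarray  # ascending property values (Å or Å²)
    y: np.ndarray  # scores in [0, 1], max exactly 1

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape or self.x.size < 2:
            raise ValueError(f"curve {self.category}: x/y must be 1-D, equal length >= 2")
        if not np.all(np.diff(self.x) > 0):
            raise ValueError(f"curve {self.category}: x values must be strictly ascending")
        if self.y.min() < 0 or not np.isclose(self.y.max(), 1.0):
            raise ValueError(f"curve {self.category}: scores must lie in [0, 1] with max 1")
        if np.any(np.diff(self.y) > 1e-12):
            raise ValueError(f"curve {self.category}: scores must be non-increasing in x")

    def score(self, value: float) -> float:
        """Linear interpolation; clamped to endpoint values outside the grid."""
        return float(np.interp(value, self.x, self.y))


class BenchmarkCurveSet:
    """Curves keyed by category; raises a named error for missing ones."""

    def __init__(self, curves: dict | None = None):
        self._curves: dict[str, BenchmarkCurve] = {}
        for key, curve in (curves or {}).items():
            self._curves[_category_key(key)] = curve

    def __len__(self):
        return len(self._curves)

    def __contains__(self, category):
        return _category_key(category) in self._curves

    def categories(self) -> list[str]:
        return sorted(self._curves)

    def add(self, curve: BenchmarkCurve) -> None:
        self._curves[curve.category] = curve

    def get(self, category) -> BenchmarkCurve:
        key = _category_key(category)
        if key not in self._curves:
            raise KeyError(f"no benchmark curve for category {key!r}")
        return self._curves[key]

    def score(self, category, value: float) -> float:
        return self.get(category).score(value)


# ---------------------------------------------------------------------------
# sample collection and fitting
# ---------------------------------------------------------------------------


def collect_samples(
    ensembles: list[StructureEnsemble],
    reference_sasa: dict[str, float] | None = None,
) -> pd.DataFrame:
    """One row per protein residue per ensemble: amino acid, exposure
    class, sidechain RMSF, trajectory-mean hydrophobic SASA."""
    if not ensembles:
        raise ValueError("need at least one ensemble")
    if reference_sasa is None:
        reference_sasa = load_reference_sasa()
    rows = []
    for ens in ensembles:
        analysis = SasaAnalysis(ens)
        classes = residue_exposure_classes(ens, analysis, reference_sasa)
        hydro = analysis.mean_hydrophobic_sasa()
        for key in ens.residue_keys:
            resname = ens.atoms[ens.residue_atoms[key][0]].residue_name
            aa = AA_3TO1[resname]
            rmsf = sidechain_rmsf(ens, key) if ens.n_frames > 1 else 0.0
            rows.append(
                {
                    "variant_id": ens.variant_id,
                    "chain": key[0],
                    "residue_number": key[1],
                    "amino_acid": aa,
                    "exposure_class": classes[key].value,
                    "sidechain_rmsf": float(rmsf),
                    "hydrophobic_sasa": float(hydro[key]),
                    "has_sidechain": aa != "G",
                }
            )
    return pd.DataFrame(rows)


def silverman_bandwidth(samples: np.ndarray) -> float:
    """h = 0.9 · min(sd, IQR/1.34) · n^(−1/5)."""
    samples = np.asarray(samples, dtype=float)
    sd = samples.std(ddof=1)
    q75, q25 = np.percentile(samples, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * samples.size ** (-1.0 / 5.0)


def suffix_max_envelope(y: np.ndarray) -> np.ndarray:
    """y'_i = max(y_j for j >= i): fills local minima from the right."""
    return np.maximum.accumulate(y[::-1])[::-1]


def fit_curve(samples, category="curve") -> BenchmarkCurve:
    """KDE-fit one category's samples into a monotone score curve.

    Gaussian KDE with Silverman bandwidth on a 512-point uniform grid
    over [0, max + 3h], scaled to max 1, then envelope-enforced.
    """
    samples = np.sort(np.asarray(samples, dtype=float))  # order-invariant sums
    key = _category_key(category)
    if samples.size < 2 or np.unique(samples).size < 2:
        raise ValueError(f"category {key!r}: need >= 2 distinct samples")
    h = silverman_bandwidth(samples)
    if h <= 0:
        raise ValueError(f"category {key!r}: zero-variance samples")
    grid = np.linspace(0.0, samples.max() + GRID_PADDING_BANDWIDTHS * h, GRID_POINTS)
    density = np.exp(-0.5 * ((grid[:, None] - samples[None, :]) / h) ** 2).sum(axis=1)
    y = density / density.max()
    y = suffix_max_envelope(y)
    y = y / y.max()
    return BenchmarkCurve(category=key, x=grid, y=y)


def build_benchmark(
    ensembles: list[StructureEnsemble] | pd.DataFrame,
    reference_sasa: dict[str, float] | None = None,
) -> tuple[BenchmarkCurveSet, BenchmarkCurveSet, dict]:
    """Fit every populated category from an ensemble collection (or a
    pre-collected sample table).

    Returns (sidechain-RMSF curve set, hydrophobic-SASA curve set,
    manifest of populated/missing categories).  Up to 20 x 3 = 60 RMSF
    categories and 20 SASA categories.
    """
    if isinstance(ensembles, pd.DataFrame):
        samples = ensembles
    else:
        samples = collect_samples(ensembles, reference_sasa)

    rmsf_set = BenchmarkCurveSet()
    sasa_set = BenchmarkCurveSet()
    manifest = {"rmsf": {"populated": [], "missing": []}, "sasa": {"populated": [], "missing": []}}

    flexible = samples[samples["has_sidechain"]]
    for aa in sorted(samples["amino_acid"].unique()):
        for cls in (ExposureClass.BURIED, ExposureClass.PARTIAL, ExposureClass.EXPOSED):
            key = _category_key((aa, cls.value))
            sub = flexible[
                (flexible["amino_acid"] == aa) & (flexible["exposure_class"] == cls.value)
            ]["sidechain_rmsf"].to_numpy()
            try:
                rmsf_set.add(fit_curve(sub, (aa, cls.value)))
                manifest["rmsf"]["populated"].append(key)
            except ValueError:
                manifest["rmsf"]["missing"].append(key)
        sub = samples[samples["amino_acid"] == aa]["hydrophobic_sasa"].to_numpy()
        try:
            sasa_set.add(fit_curve(sub, aa))
            manifest["sasa"]["populated"].append(aa)
        except ValueError:
            manifest["sasa"]["missing"].append(aa)
    for side in ("rmsf", "sasa"):
        if manifest[side]["missing"]:
            logger.warning(
                "benchmark: %d %s categories without enough samples: %s",
                len(manifest[side]["missing"]), side, manifest[side]["missing"],
            )
    return rmsf_set, sasa_set, manifest


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_curves(curve_set: BenchmarkCurveSet, path) -> None:
    """CSV with columns category,x,y, one row per grid point."""
    frames = []
    for key in curve_set.categories():
        curve = curve_set.get(key)
        frames.append(pd.DataFrame({"category": key, "x": curve.x, "y": curve.y}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


def load_curves(path) -> BenchmarkCurveSet:
    """Load and validate a curve CSV; malformed rows raise with a line number."""
    try:
        table = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed curve file {path}: {exc}") from exc
    if table.empty:
        raise ValueError(f"curve file {path} is empty")
    for col in ("category", "x", "y"):
        if col not in table.columns:
            raise ValueError(f"curve file {path} lacks required column {col!r}")
    for col in ("x", "y"):
        table[col] = pd.to_numeric(table[col], errors="coerce")
    bad = table[["x", "y"]].isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ValueError(f"curve file {path}: non-numeric value near line {line}")
    out = BenchmarkCurveSet()
    for key, group in table.groupby("category", sort=True):
        out.add(BenchmarkCurve(category=str(key), x=group["x"].to_numpy(), y=group["y"].to_numpy()))
    return out
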