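"""End-to-end orchestration: spectra + metadata in, treatment report out.

For each averaging window (short-term weeks 1-3, long-term weeks 8-10) and
each pretreatment variant, the pipeline runs: outlier screen -> region
retention -> pretreatment -> per-cow window averaging -> correlation-matrix
PCA -> eigenvalue >= 1 retention -> the trial fixed-effects model on every
retained component's scores.  Components with a significant treatment
effect get LS means, Scheffé-adjusted pairwise contrasts and — for
derivative variants — loading integration, pseudo-Voigt peak fitting and
band assignment against the molecule library.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import effects as fx
from . import interpret as itp
from . import pca as pc
from . import pretreat as pt
from . import spectra as sp
from .bands import BandLibrary, load_band_library
from .errors import InvalidArgumentError

logger = logging.getLogger("milkmir.pipeline")

__all__ = ["PipelineConfig", "VariantResult", "PipelineReport", "run_pipeline",
           "analyze_variant", "loading_features"]

#: Regions deconvolved when the integrated loading shows no clear peaks.
DEFAULT_PEAK_REGIONS = ((1180.0, 1250.0), (1250.0, 1390.0), (1424.0, 1618.0))


@dataclass
class PipelineConfig:
    """Tunable knobs of the full analysis."""

    regions: tuple = sp.DEFAULT_REGIONS
    windows: dict = field(default_factory=lambda: {
        "short": pt.SHORT_TERM_WEEKS, "long": pt.LONG_TERM_WEEKS})
    pretreatments: tuple = sp.PRETREATMENTS
    alpha: float = 0.05
    eigen_min: float = 1.0
    pct_min: float | None = None
    outlier_quantile: float = 0.999
    remove_outliers: bool = False
    peak_regions: tuple = DEFAULT_PEAK_REGIONS
    max_peaks: int = 6
    sensitivity: str = "low"
    assignment_tolerance: float = 5.0
    interpret: bool = True


@dataclass
class SignificantComponent:
    """Follow-up results for one treatment-significant component."""

    component: int  # 0-based index
    p_treatment: float
    p_start: float
    p_block: float
    clean: bool  # start and block both above alpha
    ls_means: pd.DataFrame
    contrasts: pd.DataFrame
    integrated_loading: itp.IntegratedLoading | None = None
    peak_fits: list = field(default_factory=list)
    assignments: pd.DataFrame | None = None

    @property
    def label(self) -> str:
        return f"PC{self.component + 1}"


@dataclass
class VariantResult:
    """All results for one (window, pretreatment) combination."""

    window: str
    variant: str
    model: pc.PCAModel
    retained: list
    effect_tests: pd.DataFrame  # per retained PC: eigenvalue, %, p-values
    significant: list

    @property
    def any_significant(self) -> bool:
        return len(self.significant) > 0


@dataclass
class PipelineReport:
    results: dict  # (window, variant) -> VariantResult
    outliers: pd.DataFrame
    config: PipelineConfig

    @property
    def any_significant(self) -> bool:
        return any(r.any_significant for r in self.results.values())

    def summary(self) -> dict:
        out = {"any_significant_treatment_effect": self.any_significant,
               "flagged_outliers": int(self.outliers["flagged"].sum()),
               "variants": {}}
        for (window, variant), res in self.results.items():
            sig = []
            for s in res.significant:
                entry = {
                    "component": s.label,
                    "p_treatment": round(s.p_treatment, 6),
                    "p_start": round(s.p_start, 6),
                    "p_block": round(s.p_block, 6),
                    "start_and_block_nonsignificant": s.clean,
                    "contrasts": [
                        {"pair": f"{r.level_a}-{r.level_b}",
                         "estimate": round(r.estimate, 6),
                         "p_scheffe": round(r.p_scheffe, 6)}
                        for r in s.contrasts.itertuples()
                    ],
                }
                if s.assignments is not None and len(s.assignments):
                    hits = s.assignments[s.assignments["molecule"] != "unassigned"]
                    entry["assigned_molecules"] = sorted(hits["molecule"].unique())
                sig.append(entry)
            out["variants"][f"{window}/{variant}"] = {
                "n_retained": len(res.retained),
                "significant": sig,
            }
        return out

    def to_dir(self, outdir) -> None:
        """Write CSV tables and a JSON summary; stable float formatting."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.outliers.to_csv(outdir / "outlier_screen.csv", index=False,
                             float_format="%.6g")
        for (window, variant), res in self.results.items():
            stem = f"{window}_{variant}"
            res.effect_tests.to_csv(outdir / f"{stem}_components.csv",
                                    index=False, float_format="%.6g")
            for s in res.significant:
                s.ls_means.to_csv(outdir / f"{stem}_{s.label}_lsmeans.csv",
                                  index=False, float_format="%.6g")
                s.contrasts.to_csv(outdir / f"{stem}_{s.label}_contrasts.csv",
                                   index=False, float_format="%.6g")
                if s.assignments is not None:
                    s.assignments.to_csv(
                        outdir / f"{stem}_{s.label}_assignments.csv",
                        index=False, float_format="%.6g")
                if s.integrated_loading is not None:
                    itp.plot_integrated_loading(
                        s.integrated_loading, s.assignments,
                        outdir / f"{stem}_{s.label}_integrated_loading.png")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)


def loading_features(values, grid, n_top: int = 8) -> list:
    """Extract the dominant (wavenumber, sign) features of a loading curve."""
    from scipy.signal import find_peaks

    v = np.asarray(values, dtype=float)
    feats = []
    for sl in grid.segment_slices:
        seg = np.abs(v[sl])
        idx, props = find_peaks(seg, prominence=0.05 * seg.max())
        for i in idx:
            feats.append((float(grid.points[sl.start + i]),
                          float(np.sign(v[sl.start + i])),
                          float(props["prominences"][list(idx).index(i)])))
    feats.sort(key=lambda t: -t[2])
    return [(w, s) for w, s, _ in feats[:n_top]]


def analyze_variant(averages: sp.SpectraSet, metadata: pd.DataFrame,
                    window: str, variant: str,
                    config: PipelineConfig,
                    library: BandLibrary | None = None) -> VariantResult:
    """PCA + per-component effect testing for one averaged dataset."""
    model = pc.fit_pca(averages)
    retained = pc.retain_components(model, config.eigen_min, config.pct_min)
    design = fx.cow_design(metadata).set_index("cow_id")
    design = design.loc[averages.sample_ids].reset_index()

    rows, significant = [], []
    for i in retained:
        m = fx.fit_fixed_effects(design, model.scores[:, i])
        tests = fx.type3_effect_tests(m)
        pvals = {r.effect: r.p_value for r in tests.itertuples()}
        rows.append({
            "component": f"PC{i + 1}",
            "eigenvalue": model.eigenvalues[i],
            "explained_pct": model.explained_pct[i],
            "cumulative_pct": float(np.cumsum(model.explained_pct)[i]),
            "p_treatment": pvals.get("treatment", np.nan),
            "p_start": pvals.get("start", np.nan),
            "p_block": pvals.get("block", np.nan),
        })
        if pvals.get("treatment", 1.0) <= config.alpha:
            sig = SignificantComponent(
                component=i,
                p_treatment=pvals["treatment"],
                p_start=pvals.get("start", np.nan),
                p_block=pvals.get("block", np.nan),
                clean=(pvals.get("start", 1.0) > config.alpha
                       and pvals.get("block", 1.0) > config.alpha),
                ls_means=fx.ls_means(m),
                contrasts=fx.pairwise_contrasts_scheffe(m),
            )
            if config.interpret:
                _interpret_component(sig, model, averages, variant, config,
                                     library or load_band_library())
            significant.append(sig)
    significant.sort(key=lambda s: s.p_treatment)
    return VariantResult(window=window, variant=variant, model=model,
                         retained=retained, effect_tests=pd.DataFrame(rows),
                         significant=significant)


def _interpret_component(sig, model, averages, variant, config, library):
    loading = model.loadings[:, sig.component]
    grid = averages.grid
    if variant in ("fd", "vnfd"):
        il = itp.integrate_loading(loading, grid, variant, sig.component)
        sig.integrated_loading = il
        curve = il.values
        for lo, hi in config.peak_regions:
            in_seg = any(grid.points[sl][0] - 1e-9 <= lo and hi <= grid.points[sl][-1] + 1e-9
                         for sl in grid.segment_slices)
            if not in_seg:
                continue
            try:
                sig.peak_fits.append(itp.fit_peaks(
                    curve, grid, (lo, hi), max_peaks=config.max_peaks,
                    sensitivity=config.sensitivity))
            except Exception as exc:  # partial interpretation is acceptable
                logger.warning("peak fit failed in (%s, %s): %s", lo, hi, exc)
        feats = [(float(p.center), float(np.sign(curve[grid.nearest_index(p.center)])))
                 for pf in sig.peak_fits for p in pf.peaks.itertuples()]
        feats += loading_features(curve, grid)
    else:
        feats = loading_features(loading, grid)
    # de-duplicate nearby features, keep first occurrence
    seen, uniq = [], []
    for w, s in feats:
        if all(abs(w - u) > grid.spacing for u in seen):
            seen.append(w)
            uniq.append((w, s))
    sig.assignments = itp.assign_bands(
        uniq, library, tolerance=config.assignment_tolerance,
        region_annotations=itp.DEFAULT_REGION_ANNOTATIONS)


def run_pipeline(spectra: sp.SpectraSet, metadata: pd.DataFrame,
                 config: PipelineConfig | None = None,
                 library: BandLibrary | None = None) -> PipelineReport:
    """Run the full analysis over all configured windows and variants."""
    config = config or PipelineConfig()
    meta = sp.validate_metadata(metadata)
    missing = set(spectra.sample_ids) - set(meta["sample_id"])
    if missing:
        raise InvalidArgumentError(
            f"spectra samples without metadata: {sorted(missing)[:5]}")

    t0 = time.perf_counter()
    outliers = sp.screen_outliers(spectra, config.outlier_quantile)
    logger.info("outlier screen: %d flagged (%.2fs)",
                outliers["flagged"].sum(), time.perf_counter() - t0)
    if config.remove_outliers and outliers["flagged"].any():
        keep = ~np.asarray(outliers["flagged"])
        spectra = sp.SpectraSet(
            sample_ids=[s for s, k in zip(spectra.sample_ids, keep) if k],
            grid=spectra.grid, values=spectra.values[keep],
            pretreatment=spectra.pretreatment)

    selected = sp.select_regions(spectra, config.regions)
    variants = pt.make_pretreatment_variants(selected)
    library = library or load_band_library()

    results = {}
    for window, weeks in config.windows.items():
        for name in config.pretreatments:
            t1 = time.perf_counter()
            averages = pt.window_average(variants[name], meta, weeks)
            res = analyze_variant(averages, meta, window, name, config, library)
            results[(window, name)] = res
            logger.info("%s/%s: %d retained, %d significant (%.2fs)",
                        window, name, len(res.retained), len(res.significant),
                        time.perf_counter() - t1)
    return PipelineReport(results=results, outliers=outliers, config=config)
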