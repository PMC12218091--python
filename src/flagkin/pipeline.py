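"""Orchestration: run full recordings, aggregate cells to animals, compare
genotypes on animal means, and compute population flexibility breakdowns.

Statistics follow the per-animal design of tethered-sperm studies: cells are
technical replicates, so every comparison first averages within animal and
then runs an unpaired two-sample Student t-test across animals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    CenterlineSeries,
    FlexibilityClass,
    KinematicSummary,
    STIFF_CLASSES,
    SectionBoundaries,
)
from .energetics import MaterialParams, compute_energetics
from .errors import (
    DegenerateCycleError,
    EmptySetError,
    FlagkinError,
    InsufficientGroupsError,
    InsufficientRecordError,
    RankError,
    SegmentationError,
    TraceError,
)
from .kinematics import classify_flexibility, section_amplitude, summarize
from .render import OpticsParams, SyntheticScene, render_frames
from .shape_modes import fit_shape_modes
from .simulate import PopulationSpec, sample_population, simulate_beat
from .trace import TraceConfig, to_waveform, trace_scene

__all__ = [
    "CellRecord",
    "GroupComparison",
    "run_recording",
    "run_population",
    "population_breakdown",
    "compare_groups",
    "records_to_frame",
]


@dataclass
class CellRecord:
    """One recording's full read-out plus QC provenance."""

    cell_id: str
    animal_id: str = ""
    genotype: str = ""
    summary: KinematicSummary | None = None
    energetics_fw: dict[str, float] | None = None
    circularity: float | None = None
    qc: dict = field(default_factory=dict)


@dataclass
class GroupComparison:
    """Animal-level comparison of one quantity between two groups."""

    quantity: str
    group_a: str
    group_b: str
    animal_means_a: dict[str, float]
    animal_means_b: dict[str, float]
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    p: float
    welch: bool
    excluded_animals: list[str] = field(default_factory=list)

    @property
    def n_a(self) -> int:
        return len(self.animal_means_a)

    @property
    def n_b(self) -> int:
        return len(self.animal_means_b)


def _load_input(source) -> tuple[SyntheticScene | None, CenterlineSeries | None]:
    from . import io as fio

    if isinstance(source, SyntheticScene):
        return source, None
    if isinstance(source, CenterlineSeries):
        return None, source
    path = Path(source)
    if path.suffix.lower() in (".tif", ".tiff"):
        return fio.read_scene_tiff(path), None
    if path.suffix.lower() in (".csv", ".txt"):
        return None, fio.read_series_csv(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return None, fio.read_series_h5(path)
    raise FlagkinError(f"unrecognised input {path}")


def run_recording(source, trace_config: TraceConfig | None = None,
                  bounds: SectionBoundaries | None = None,
                  material: MaterialParams | None = None,
                  cell_id: str = "cell", animal_id: str = "", genotype: str = "",
                  amplitude_smooth_window: int = 1,
                  energetics_smooth_window: int = 5,
                  with_energetics: bool = True,
                  with_shape_modes: bool = True) -> CellRecord:
    """Full analysis chain for one recording.

    ``source`` may be a :class:`SyntheticScene`, a :class:`CenterlineSeries`
    (simulated ground truth or pre-traced table) or a path to a TIFF stack /
    centerline CSV / HDF5.  Stage failures are recorded as QC flags instead
    of aborting; only unreadable input raises.
    """
    bounds = bounds or SectionBoundaries()
    record = CellRecord(cell_id=cell_id, animal_id=animal_id, genotype=genotype)
    scene, series = _load_input(source)
    if scene is not None:
        try:
            series, qc = trace_scene(scene, trace_config)
            record.qc.update(qc)
        except (TraceError, SegmentationError) as exc:
            record.qc.update({"rejected": True, "reason": str(exc)})
            return record
    assert series is not None
    record.qc.setdefault("frames_total", series.n_frames)
    record.qc.setdefault("frames_traced", series.n_frames)
    waveform = to_waveform(series)
    record.summary = summarize(series, waveform, bounds,
                               smooth_window=amplitude_smooth_window)
    if with_shape_modes:
        try:
            cycle = fit_shape_modes(waveform, k=2)
            record.circularity = cycle.circularity
        except (RankError, DegenerateCycleError) as exc:
            record.qc["shape_modes"] = str(exc)
    if with_energetics:
        try:
            profile = compute_energetics(series, waveform, material, bounds,
                                         smooth_window=energetics_smooth_window)
            f = record.summary.beat_frequency
            if np.isfinite(f) and f > 0:
                record.energetics_fw = profile.cycle_averages(f)
            else:
                record.energetics_fw = {k: 0.0 for k in
                                        ("p_in", "d_m", "d_i", "d_h",
                                         "d_h_head", "d_h_mid", "d_h_principal")}
                record.qc["energetics"] = "no beat frequency; powers reported as 0"
        except (FlagkinError, InsufficientRecordError) as exc:
            record.qc["energetics"] = str(exc)
    return record


def run_population(spec: PopulationSpec, snr: float | None = 10.0,
                   fps: float = 250.0, duration: float = 4.0,
                   sim_ds: float = 1.0,
                   trace_config: TraceConfig | None = None,
                   bounds: SectionBoundaries | None = None,
                   optics: OpticsParams | None = None,
                   amplitude_smooth_window: int = 1,
                   progress: bool = False) -> pd.DataFrame:
    """Generate, render, trace and classify a labelled population.

    For every sampled cell the beat is simulated, rendered at the requested
    crest SNR, traced frame by frame and classified from its traced midpiece
    amplitude.  ``snr=None`` skips rendering and classifies the ground-truth
    centerlines directly (noise-free reference).  Returns one row per cell
    with the true category, measured amplitude and predicted category.
    """
    bounds = bounds or SectionBoundaries()
    trace_config = trace_config or TraceConfig()
    if snr is not None and optics is None:
        optics = OpticsParams.for_snr(snr)
    cells = sample_population(spec, fps=fps, duration=duration, bounds=bounds)
    rows = []
    for i, (params, cat) in enumerate(cells):
        series = simulate_beat(params, ds=sim_ds)
        amp = np.nan
        pred = None
        status = "ok"
        if optics is None:
            amp = section_amplitude(series, bounds, amplitude_smooth_window)["mid"]
        else:
            scene = render_frames(series, optics, seed=params.seed)
            try:
                traced, _ = trace_scene(scene, trace_config)
                amp = section_amplitude(traced, bounds, amplitude_smooth_window)["mid"]
            except (TraceError, SegmentationError) as exc:
                status = f"trace failed: {exc}"
        if np.isfinite(amp):
            pred = classify_flexibility(amp)
        rows.append({
            "cell": i,
            "true_class": cat.value,
            "amplitude_mid": amp,
            "pred_class": pred.value if pred is not None else None,
            "beat_frequency": params.beat_frequency,
            "status": status,
        })
        if progress and (i + 1) % 50 == 0:
            print(f"  {i + 1}/{len(cells)} cells", flush=True)
    return pd.DataFrame(rows)


def population_breakdown(classes) -> dict[str, float]:
    """Percentage of records per flexibility class, plus the combined
    'stiff' percentage (moderately + highly stiff).

    ``classes`` may be an iterable of :class:`FlexibilityClass`, class value
    strings, or :class:`CellRecord` objects.
    """
    vals: list[str] = []
    for c in classes:
        if isinstance(c, CellRecord):
            if c.summary is None:
                continue
            vals.append(c.summary.flexibility_class.value)
        elif isinstance(c, FlexibilityClass):
            vals.append(c.value)
        elif isinstance(c, str) and c:
            vals.append(c)
    if not vals:
        raise EmptySetError("no classified records")
    n = len(vals)
    out = {cls.value: 100.0 * vals.count(cls.value) / n for cls in FlexibilityClass}
    out["stiff"] = sum(out[c.value] for c in STIFF_CLASSES)
    return out


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    """Flatten cell records into a tidy per-cell DataFrame."""
    rows = []
    for r in records:
        row: dict = {"cell_id": r.cell_id, "animal_id": r.animal_id,
                     "genotype": r.genotype,
                     "frames_traced": r.qc.get("frames_traced"),
                     "rejected": bool(r.qc.get("rejected", False))}
        if r.summary is not None:
            row.update({
                "beat_frequency": r.summary.beat_frequency,
                "amplitude_mid": r.summary.amplitude_mid,
                "amplitude_principal": r.summary.amplitude_principal,
                "flexibility_class": r.summary.flexibility_class.value,
            })
        if r.circularity is not None:
            row["circularity"] = r.circularity
        if r.energetics_fw:
            row.update({f"{k}_fw": v for k, v in r.energetics_fw.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(records, quantity: str, group_col: str = "genotype",
                   animal_col: str = "animal_id",
                   welch: bool = False) -> GroupComparison:
    """Two-group comparison of ``quantity`` on animal means.

    Cells are averaged within animal first; the test is an unpaired
    two-sample Student t-test (equal variance) across animals, or Welch's
    variant when ``welch=True``.  Animals without a single valid cell value
    are excluded with a warning.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if quantity not in df.columns:
        raise FlagkinError(f"quantity '{quantity}' not in records")
    groups = sorted(df[group_col].dropna().unique())
    if len(groups) != 2:
        raise InsufficientGroupsError(f"need exactly 2 groups, found {groups}")
    excluded: list[str] = []
    means: dict[str, dict[str, float]] = {}
    for g in groups:
        sub = df[df[group_col] == g]
        by_animal = sub.groupby(animal_col)[quantity].mean()
        bad = by_animal[~np.isfinite(by_animal)].index.tolist()
        if bad:
            warnings.warn(f"excluding animals without valid '{quantity}': {bad}")
            excluded.extend(str(b) for b in bad)
        by_animal = by_animal[np.isfinite(by_animal)]
        if len(by_animal) < 2:
            raise InsufficientGroupsError(
                f"group '{g}' has {len(by_animal)} animals with data (need >= 2)"
            )
        means[g] = {str(k): float(v) for k, v in by_animal.items()}
    a_vals = np.array(list(means[groups[0]].values()))
    b_vals = np.array(list(means[groups[1]].values()))
    t, p = sps.ttest_ind(a_vals, b_vals, equal_var=not welch)
    return GroupComparison(
        quantity=quantity, group_a=str(groups[0]), group_b=str(groups[1]),
        animal_means_a=means[groups[0]], animal_means_b=means[groups[1]],
        mean_a=float(a_vals.mean()), sd_a=float(a_vals.std(ddof=1)),
        mean_b=float(b_vals.mean()), sd_b=float(b_vals.std(ddof=1)),
        t=float(t), p=float(p), welch=welch, excluded_animals=excluded,
    )
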