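"""Per-plate mean + k·SD hit calling with dual-read concordance.

The hit rule: on every plate and in every read, summarize the M1
solvent-control wells (mean m, sample SD); a compound is an activator hit
when its signal strictly exceeds m + k·SD in *every* read (default k = 3),
with thresholds never pooled across plates or reads.  A parallel viability
counterscreen flags compounds whose signal change merely reflects
cytotoxicity.

The model surface follows the statsmodels convention:
``HitCallingModel(dataset, k=3).fit()`` returns a :class:`HitCallingResults`
with the per-compound call table, per-plate control summaries, screen-level
QC (control CVs, Z' between M0 and solvent controls), and a ``summary()``
table.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings

import numpy as np
import pandas as pd

from .errors import InsufficientControlsError
from .plates import PlateLayout, PlateRead, ScreenDataset, WellRole
from .qc import z_factor

logger = logging.getLogger(__name__)

DEFAULT_K = 3.0
DEFAULT_VIABILITY_CUTOFF = 0.7


@dataclasses.dataclass
class ControlSummary:
    """Mean/SD/n of one control role on one plate in one read."""

    plate_id: str
    read_index: int
    role: WellRole
    m: float
    sd: float
    n: int

    @property
    def cv_percent(self) -> float:
        return 100.0 * self.sd / self.m if self.m > 0 else float("nan")


@dataclasses.dataclass
class HitThreshold:
    """Symmetric m ± k·SD decision band around the solvent-control mean."""

    plate_id: str
    read_index: int
    k: float
    m: float
    sd: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"threshold multiplier k must be >= 0, got {self.k}")

    @property
    def upper(self) -> float:
        return self.m + self.k * self.sd

    @property
    def lower(self) -> float:
        return self.m - self.k * self.sd


@dataclasses.dataclass
class HitCall:
    """Per-compound decision record across reads."""

    compound_id: str
    library: str
    plate_id: str
    well: str
    direction: str  # "activator" | "inhibitor"
    signals: dict[int, float]
    thresholds: dict[int, HitThreshold]
    exceeds: dict[int, bool]
    status: str  # "hit" | "no_hit" | "incomplete"
    viability_flag: str = "none"  # none | reduced_viability | viability_confounded | unassessed
    relative_viability: float | None = None


def summarize_controls(
    read: PlateRead, layout: PlateLayout, role: WellRole = WellRole.M1_SOLVENT
) -> ControlSummary:
    """Mean and sample SD of one control role's signals on a plate/read.

    Wells with missing or non-finite signals are excluded with a warning;
    fewer than two usable wells is an error because the SD is undefined.
    """
    wells = layout.wells_of_role(role)
    values = []
    for well in wells:
        v = read.signal.get(well)
        if v is None or not math.isfinite(v):
            logger.warning(
                "plate %s read %d: %s well %s missing/non-finite, excluded",
                read.plate_id,
                read.read_index,
                role.name,
                well,
            )
            continue
        values.append(v)
    if len(values) < 2:
        raise InsufficientControlsError(
            f"plate {read.plate_id!r} read {read.read_index}: "
            f"{len(values)} usable {role.name} wells (need >=2)"
        )
    arr = np.asarray(values, dtype=float)
    return ControlSummary(
        plate_id=read.plate_id,
        read_index=read.read_index,
        role=role,
        m=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        n=len(arr),
    )


def activation_threshold(summary: ControlSummary, k: float = DEFAULT_K) -> HitThreshold:
    """Build the m ± k·SD hit threshold from a solvent-control summary."""
    return HitThreshold(
        plate_id=summary.plate_id,
        read_index=summary.read_index,
        k=k,
        m=summary.m,
        sd=summary.sd,
    )


def call_compound(
    compound_id: str,
    signals: dict[int, float],
    thresholds: dict[int, HitThreshold],
    direction: str = "activator",
    expected_reads: int | None = None,
    library: str = "",
    plate_id: str = "",
    well: str = "",
) -> HitCall:
    """Apply the dual-read rule to one compound.

    Exceedance is strict: an activator must have signal > upper in a read, an
    inhibitor signal < lower; a signal exactly on the threshold is not a hit.
    A compound missing any configured read is ``incomplete``, never a hit.
    """
    if direction not in ("activator", "inhibitor"):
        raise ValueError(f"unknown direction {direction!r}")
    n_expected = expected_reads if expected_reads is not None else len(thresholds)
    exceeds: dict[int, bool] = {}
    for idx, thr in sorted(thresholds.items()):
        if idx not in signals:
            continue
        sig = signals[idx]
        exceeds[idx] = sig > thr.upper if direction == "activator" else sig < thr.lower
    if len(exceeds) < n_expected:
        status = "incomplete"
    else:
        status = "hit" if exceeds and all(exceeds.values()) else "no_hit"
    return HitCall(
        compound_id=compound_id,
        library=library,
        plate_id=plate_id,
        well=well,
        direction=direction,
        signals=dict(sorted(signals.items())),
        thresholds=thresholds,
        exceeds=exceeds,
        status=status,
    )


def call_screen(
    dataset: ScreenDataset,
    k: float = DEFAULT_K,
    direction: str = "activator",
    expected_reads: int | None = None,
) -> tuple[list[HitCall], list[ControlSummary]]:
    """Call every compound in a screen; thresholds are per plate and per read.

    Returns the calls in deterministic (library, plate, well) order together
    with the solvent-control summaries that defined the thresholds.
    Inhibitor calling emits a warning: a wide control spread (high CV,
    negative Z') limits the power to detect signal decreases.
    """
    if direction == "inhibitor":
        warnings.warn(
            "inhibitor calling requested: with noisy solvent controls the "
            "assay has limited power to identify inhibitory compounds",
            stacklevel=2,
        )
    read_indices = dataset.read_indices()
    n_expected = expected_reads if expected_reads is not None else len(read_indices)

    summaries: list[ControlSummary] = []
    thresholds: dict[tuple[str, int], HitThreshold] = {}
    failures = []
    for (plate, idx), read in sorted(dataset.reads.items()):
        try:
            summ = summarize_controls(read, dataset.layouts[plate], WellRole.M1_SOLVENT)
        except InsufficientControlsError as exc:
            failures.append(str(exc))
            continue
        summaries.append(summ)
        thresholds[(plate, idx)] = activation_threshold(summ, k)
    if failures:
        raise InsufficientControlsError("; ".join(failures))

    lib_key = {
        (r.compound_id, r.plate_id): r.library
        for r in dataset.library_registry.itertuples(index=False)
    }
    lib_any = dict(
        zip(dataset.library_registry["compound_id"], dataset.library_registry["library"])
    )

    calls: list[HitCall] = []
    for plate, layout in dataset.layouts.items():
        plate_thresholds = {
            idx: thresholds[(plate, idx)]
            for idx in read_indices
            if (plate, idx) in thresholds
        }
        for well, cid in layout.compound_wells().items():
            signals = {
                idx: dataset.reads[(plate, idx)].signal[well]
                for idx in read_indices
                if (plate, idx) in dataset.reads
                and well in dataset.reads[(plate, idx)].signal
            }
            calls.append(
                call_compound(
                    cid,
                    signals,
                    plate_thresholds,
                    direction=direction,
                    expected_reads=n_expected,
                    library=lib_key.get((cid, plate), lib_any.get(cid, "")),
                    plate_id=plate,
                    well=str(well),
                )
            )
    calls.sort(key=lambda c: (c.library, c.plate_id, c.well))
    return calls, summaries


@dataclasses.dataclass
class ViabilityRecord:
    """One compound's counterscreen measurement relative to solvent controls."""

    compound_id: str
    viability: float
    control_mean: float

    @property
    def relative_viability(self) -> float:
        return self.viability / self.control_mean


def flag_viability(
    calls: list[HitCall],
    dataset: ScreenDataset,
    cutoff: float = DEFAULT_VIABILITY_CUTOFF,
    viability_read: int | None = None,
) -> list[HitCall]:
    """Annotate calls with the cytotoxicity counterscreen.

    Relative viability is the compound well's viability signal divided by the
    plate's M1 solvent-control viability mean in the read that carried the
    counterscreen.  Below ``cutoff`` the call is flagged
    ``reduced_viability``; if additionally the compound's reporter signal in
    that read fell below the solvent-control mean, the flag is
    ``viability_confounded`` (signal loss explainable by cell death).  Hits
    keep their hit status either way — the flag is an annotation, not a veto.
    """
    viab_reads = {
        key: pr for key, pr in dataset.reads.items() if pr.viability
    }
    if viability_read is not None:
        viab_reads = {k: v for k, v in viab_reads.items() if k[1] == viability_read}

    control_means: dict[tuple[str, int], float] = {}
    for (plate, idx), pr in viab_reads.items():
        wells = dataset.layouts[plate].wells_of_role(WellRole.M1_SOLVENT)
        vals = [pr.viability[w] for w in wells if w in pr.viability]
        if len(vals) >= 2:
            control_means[(plate, idx)] = float(np.mean(vals))

    for call in calls:
        measured = False
        for (plate, idx), pr in sorted(viab_reads.items()):
            if plate != call.plate_id or (plate, idx) not in control_means:
                continue
            from .plates import WellAddress

            well = WellAddress.parse(call.well)
            if well not in pr.viability:
                continue
            measured = True
            rel = pr.viability[well] / control_means[(plate, idx)]
            call.relative_viability = rel
            if rel < cutoff:
                thr = call.thresholds.get(idx)
                sig = call.signals.get(idx)
                below_control_mean = (
                    thr is not None and sig is not None and sig < thr.m
                )
                call.viability_flag = (
                    "viability_confounded" if below_control_mean else "reduced_viability"
                )
            else:
                call.viability_flag = "none"
        if not measured:
            if call.status == "hit":
                logger.warning(
                    "hit compound %s has no viability measurement", call.compound_id
                )
            call.viability_flag = "unassessed"
    return calls


def calls_to_frame(calls: list[HitCall]) -> pd.DataFrame:
    """Flatten calls to a tidy table, one row per compound."""
    read_indices = sorted({idx for c in calls for idx in c.thresholds})
    rows = []
    for c in calls:
        row: dict = {
            "compound_id": c.compound_id,
            "library": c.library,
            "plate_id": c.plate_id,
            "well": c.well,
            "direction": c.direction,
            "status": c.status,
            "viability_flag": c.viability_flag,
            "relative_viability": c.relative_viability,
        }
        for idx in read_indices:
            row[f"signal_read{idx}"] = c.signals.get(idx)
            thr = c.thresholds.get(idx)
            row[f"threshold_read{idx}"] = thr.upper if thr else None
            row[f"exceeds_read{idx}"] = c.exceeds.get(idx)
        rows.append(row)
    return pd.DataFrame(rows)


class HitCallingModel:
    """Per-plate mean + k·SD dual-read hit-calling model for a screen.

    Parameters
    ----------
    dataset
        Assembled screen (layouts, reads, library registry).
    k
        SD multiplier for the decision band (default 3).
    direction
        "activator" (default; the screen design has little power for
        inhibitors) or "inhibitor".
    viability_cutoff
        Fraction of the solvent-control viability mean below which a
        compound is flagged cytotoxic (default 0.7).
    """

    def __init__(
        self,
        dataset: ScreenDataset,
        k: float = DEFAULT_K,
        direction: str = "activator",
        viability_cutoff: float = DEFAULT_VIABILITY_CUTOFF,
    ) -> None:
        if k < 0:
            raise ValueError("k must be non-negative")
        self.dataset = dataset
        self.k = k
        self.direction = direction
        self.viability_cutoff = viability_cutoff

    def fit(self) -> "HitCallingResults":
        calls, summaries = call_screen(self.dataset, self.k, self.direction)
        calls = flag_viability(calls, self.dataset, self.viability_cutoff)
        qc = self._screen_qc(summaries)
        return HitCallingResults(self, calls, summaries, qc)

    def _screen_qc(self, solvent_summaries: list[ControlSummary]) -> pd.DataFrame:
        """Per plate/read control CVs and Z' between M0 and solvent controls."""
        rows = []
        for summ in solvent_summaries:
            plate, idx = summ.plate_id, summ.read_index
            read = self.dataset.reads[(plate, idx)]
            layout = self.dataset.layouts[plate]
            row = {
                "plate_id": plate,
                "read_index": idx,
                "m1_solvent_mean": summ.m,
                "m1_solvent_sd": summ.sd,
                "m1_solvent_cv_percent": summ.cv_percent,
                "m0_cv_percent": np.nan,
                "z_factor_m0_vs_m1": np.nan,
            }
            try:
                m0 = summarize_controls(read, layout, WellRole.M0_CONTROL)
                row["m0_cv_percent"] = m0.cv_percent
                m0_vals = [read.signal[w] for w in layout.wells_of_role(WellRole.M0_CONTROL) if w in read.signal]
                m1_vals = [read.signal[w] for w in layout.wells_of_role(WellRole.M1_SOLVENT) if w in read.signal]
                z = z_factor(m1_vals, m0_vals)
                row["z_factor_m0_vs_m1"] = z
                if z < 0:
                    logger.warning(
                        "plate %s read %d: negative Z' (%.2f) — control "
                        "distributions overlap, hit calls are low-confidence",
                        plate,
                        idx,
                        z,
                    )
            except Exception:
                pass
            rows.append(row)
        return pd.DataFrame(rows).sort_values(["plate_id", "read_index"]).reset_index(drop=True)


class HitCallingResults:
    """Fitted hit-calling results: call table, thresholds, screen QC."""

    def __init__(
        self,
        model: HitCallingModel,
        calls: list[HitCall],
        control_summaries: list[ControlSummary],
        plate_qc: pd.DataFrame,
    ) -> None:
        self.model = model
        self.calls = calls
        self.control_summaries = control_summaries
        self.plate_qc = plate_qc

    @property
    def table(self) -> pd.DataFrame:
        return calls_to_frame(self.calls)

    @property
    def hits(self) -> list[HitCall]:
        return [c for c in self.calls if c.status == "hit"]

    @property
    def hit_ids(self) -> set[str]:
        return {c.compound_id for c in self.hits}

    def status_counts(self) -> dict[str, int]:
        counts = {"hit": 0, "no_hit": 0, "incomplete": 0}
        for c in self.calls:
            counts[c.status] += 1
        return counts

    def summary(self) -> str:
        counts = self.status_counts()
        lines = [
            "Hit-calling results",
            "===================",
            f"compounds: {len(self.calls)}   k = {self.model.k:g}   "
            f"direction = {self.model.direction}   "
            f"viability cutoff = {self.model.viability_cutoff:g}",
            f"hits: {counts['hit']}   no_hit: {counts['no_hit']}   "
            f"incomplete: {counts['incomplete']}",
            "",
            "Per-plate controls (solvent CV %, M0 CV %, Z' M0 vs M1):",
        ]
        for r in self.plate_qc.itertuples(index=False):
            lines.append(
                f"  {r.plate_id} read {r.read_index}: "
                f"CV(M1)={r.m1_solvent_cv_percent:6.1f}  "
                f"CV(M0)={r.m0_cv_percent:6.1f}  Z'={r.z_factor_m0_vs_m1:6.2f}"
            )
        if self.hits:
            lines.append("")
            lines.append("Hits:")
            for c in self.hits:
                rv = (
                    f"rel.viability={c.relative_viability:.2f}"
                    if c.relative_viability is not None
                    else "viability unassessed"
                )
                lines.append(
                    f"  {c.compound_id} ({c.library}, {c.plate_id}/{c.well}) "
                    f"[{c.viability_flag}] {rv}"
                )
        return "\n".join(lines)
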