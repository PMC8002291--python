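"""Seeded generators for truth-labelled synthetic screening data.

The generators emit the data structures the analysis modules consume —
full screening decks, dilution series, and qPCR Ct tables — together with a
:class:`SimTruth` record of every planted effect, so sensitivity and
specificity of any downstream caller can be scored exactly.

Noise model
-----------
Well signals are multiplicative log-normal: a well's signal is
``read_scale · role_multiplier · compound_effect · ε`` with
``ε = exp(σZ − σ²/2)`` and ``σ = sqrt(ln(1 + CV²))``, i.e. a mean-one
log-normal whose coefficient of variation equals the configured CV, so the
configured baselines are the exact means of the generated distributions.
The two reads share each compound's true effect but draw measurement noise
independently — read-to-read correlation enters only through the biology,
mirroring a screen whose raw read correlation was weak.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .errors import ConfigError
from .plates import (
    PlateLayout,
    PlateRead,
    ScreenDataset,
    WellAddress,
    WellRole,
    N_COLS,
    N_ROWS,
)
from .qc import DilutionSeries, ReplicateSet

_ROW_LETTERS = "ABCDEFGHIJKLMNOP"


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative noise with the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, size) - sigma * sigma / 2.0)


@dataclasses.dataclass
class SimTruth:
    """Ground truth planted into a synthetic dataset."""

    effects: dict[str, float] = dataclasses.field(default_factory=dict)
    cytotoxicity: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=dict
    )  # compound -> (viability fraction, signal fraction)
    true_folds: dict[tuple[str, str], float] = dataclasses.field(
        default_factory=dict
    )  # (gene, condition) -> fold vs control

    def to_dict(self) -> dict:
        return {
            "effects": dict(sorted(self.effects.items())),
            "cytotoxicity": {
                k: list(v) for k, v in sorted(self.cytotoxicity.items())
            },
            "true_folds": {
                f"{g}/{c}": f for (g, c), f in sorted(self.true_folds.items())
            },
        }


@dataclasses.dataclass
class ScreenSimConfig:
    """Configuration of a synthetic screening deck.

    Defaults mirror a 2054-compound, seven-plate, two-read 384-well screen:
    four plates of 320 compounds (library LOPAC) and three of 258 (library
    ENZO); per plate 16 M0 background controls, 16 M1 solvent controls and 8
    M1 positive (TSA) controls; per-read control CVs of 0.45 (read 1,
    phenol-red medium) and 0.30 (read 2, phenol-red-free, which also runs
    the viability counterscreen at double baseline scale).
    """

    compounds_per_plate: tuple[int, ...] = (320, 320, 320, 320, 258, 258, 258)
    libraries: tuple[str, ...] = ("LOPAC", "LOPAC", "LOPAC", "LOPAC", "ENZO", "ENZO", "ENZO")
    n_m0: int = 16
    n_solvent: int = 16
    n_tsa: int = 8
    reads: int = 2
    m0_baseline: float = 1000.0
    solvent_multiplier: float = 3.0
    tsa_multiplier: float = 8.0
    read_cv: tuple[float, ...] = (0.45, 0.30)
    read_scale: tuple[float, ...] = (1.0, 2.0)
    viability_baseline: float = 50000.0
    viability_cv: float = 0.10
    viability_read: int = 2
    planted_hits: tuple[tuple[int, float], ...] = ()
    planted_cytotoxics: tuple[tuple[int, float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.libraries) != len(self.compounds_per_plate):
            raise ConfigError("one library name required per plate")
        if len(self.read_cv) != self.reads or len(self.read_scale) != self.reads:
            raise ConfigError("read_cv and read_scale must have one entry per read")
        if any(cv < 0 for cv in self.read_cv) or self.viability_cv < 0:
            raise ConfigError("CVs must be non-negative")
        if min(
            self.m0_baseline,
            self.solvent_multiplier,
            self.tsa_multiplier,
            *self.read_scale,
        ) <= 0:
            raise ConfigError("baselines, multipliers and scales must be positive")
        n_slots = sum(self.compounds_per_plate)
        slots = [s for s, _ in self.planted_hits] + [
            s for s, _, _ in self.planted_cytotoxics
        ]
        if any(not 0 <= s < n_slots for s in slots):
            raise ConfigError(
                f"planted slot out of range: {n_slots} compound wells available"
            )
        per_plate_capacity = N_ROWS * N_COLS - self.n_m0 - self.n_solvent - self.n_tsa
        if any(n > per_plate_capacity for n in self.compounds_per_plate):
            raise ConfigError(
                f"more planted compound wells than available ({per_plate_capacity})"
            )
        if any(m <= 0 for _, m in self.planted_hits):
            raise ConfigError("effect multipliers must be positive")


def default_screen_config(seed: int = 0, **overrides) -> ScreenSimConfig:
    """The packaged default: 2054 compounds, 3 planted 5× activators and 4
    planted cytotoxics, emulating the screen the analysis was built for."""
    params = dict(
        planted_hits=((101, 5.0), (951, 5.0), (1600, 5.0)),
        planted_cytotoxics=(
            (250, 0.25, 0.3),
            (700, 0.30, 0.35),
            (1300, 0.20, 0.25),
            (1900, 0.35, 0.4),
        ),
        seed=seed,
    )
    params.update(overrides)
    return ScreenSimConfig(**params)


def _plate_layout(
    plate_id: str, n_compounds: int, cfg: ScreenSimConfig, compound_ids: list[str]
) -> PlateLayout:
    """Deterministic layout: controls first (column-major), then compounds."""
    addresses = [
        WellAddress(r, c) for c in range(1, N_COLS + 1) for r in _ROW_LETTERS
    ]
    wells: dict[WellAddress, tuple[WellRole, str | None]] = {}
    cursor = 0
    for role, count in (
        (WellRole.M0_CONTROL, cfg.n_m0),
        (WellRole.M1_SOLVENT, cfg.n_solvent),
        (WellRole.M1_TSA, cfg.n_tsa),
    ):
        for _ in range(count):
            wells[addresses[cursor]] = (role, None)
            cursor += 1
    for cid in compound_ids:
        wells[addresses[cursor]] = (WellRole.COMPOUND, cid)
        cursor += 1
    for addr in addresses[cursor:]:
        wells[addr] = (WellRole.EMPTY, None)
    return PlateLayout(plate_id, wells)


def simulate_screen(
    config: ScreenSimConfig, seed: int | None = None
) -> tuple[ScreenDataset, SimTruth]:
    """Generate a truth-labelled synthetic screen.

    Signals follow the module's multiplicative log-normal model; the reads
    draw independent noise around each compound's shared true effect.
    Viability is emitted for the configured counterscreen read: a compound's
    viability is the control viability baseline times its planted viability
    fraction (1 for healthy compounds), and a cytotoxic compound's reporter
    signal is additionally depressed by its planted signal fraction.
    Identical config and seed give bit-identical output.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    truth = SimTruth()

    effect = {}
    viab_frac = {}
    n_slots = sum(config.compounds_per_plate)
    compound_ids = [f"CPD-{i:05d}" for i in range(n_slots)]
    for slot, mult in config.planted_hits:
        effect[compound_ids[slot]] = mult
    for slot, vfrac, sfrac in config.planted_cytotoxics:
        cid = compound_ids[slot]
        if cid in effect:
            raise ConfigError(f"slot {slot} planted as both hit and cytotoxic")
        effect[cid] = sfrac
        viab_frac[cid] = vfrac
        truth.cytotoxicity[cid] = (vfrac, sfrac)
    for cid in compound_ids:
        truth.effects[cid] = effect.get(cid, 1.0)

    layouts: dict[str, PlateLayout] = {}
    reads: dict[tuple[str, int], PlateRead] = {}
    registry_rows = []
    slot = 0
    for p, (n_cpd, library) in enumerate(
        zip(config.compounds_per_plate, config.libraries), start=1
    ):
        plate_id = f"P{p}"
        cids = compound_ids[slot : slot + n_cpd]
        slot += n_cpd
        layout = _plate_layout(plate_id, n_cpd, config, cids)
        layouts[plate_id] = layout
        for well, cid in layout.compound_wells().items():
            registry_rows.append(
                {"compound_id": cid, "library": library, "plate_id": plate_id, "well": str(well)}
            )

        role_mult = {
            WellRole.M0_CONTROL: 1.0,
            WellRole.M1_SOLVENT: config.solvent_multiplier,
            WellRole.M1_TSA: config.tsa_multiplier,
            WellRole.COMPOUND: config.solvent_multiplier,
        }
        wells_sorted = [w for w in sorted(layout.wells) if layout.wells[w][0] is not WellRole.EMPTY]
        for r in range(1, config.reads + 1):
            cv = config.read_cv[r - 1]
            scale = config.read_scale[r - 1]
            noise = _lognormal_factor(rng, cv, len(wells_sorted))
            signal: dict[WellAddress, float] = {}
            for w, eps in zip(wells_sorted, noise):
                role, cid = layout.wells[w]
                mean = config.m0_baseline * scale * role_mult[role]
                if role is WellRole.COMPOUND and cid is not None:
                    mean *= truth.effects[cid]
                signal[w] = mean * eps
            viability = None
            if r == config.viability_read:
                vnoise = _lognormal_factor(rng, config.viability_cv, len(wells_sorted))
                viability = {}
                for w, eps in zip(wells_sorted, vnoise):
                    role, cid = layout.wells[w]
                    frac = viab_frac.get(cid, 1.0) if cid else 1.0
                    viability[w] = config.viability_baseline * frac * eps
            reads[(plate_id, r)] = PlateRead(
                plate_id, r, signal, viability,
                medium_tag="phenol-red" if r == 1 else "phenol-red-free",
            )

    registry = pd.DataFrame(
        registry_rows, columns=["compound_id", "library", "plate_id", "well"]
    ).sort_values(["library", "plate_id", "well", "compound_id"]).reset_index(drop=True)
    return ScreenDataset(layouts=layouts, reads=reads, library_registry=registry), truth


def simulate_dilution_series(
    base_signal: float = 1.0e6,
    n_decades: int = 5,
    cv_profile: float | list[float] = 0.05,
    background: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[DilutionSeries, dict]:
    """A serial 10-fold dilution with replicate noise and background floor.

    Level means are ``base/10^d + background``; the truth dict records the
    base signal and background so the expected linear range is known.
    """
    if n_decades < 3:
        raise ConfigError("need at least 3 dilution levels")
    rng = np.random.default_rng(seed)
    cvs = (
        [float(cv_profile)] * n_decades
        if np.isscalar(cv_profile)
        else list(cv_profile)
    )
    factors = [10.0**d for d in range(n_decades)]
    sets = []
    for factor, cv in zip(factors, cvs):
        mean = base_signal / factor + background
        values = mean * _lognormal_factor(rng, cv, n_replicates)
        sets.append(ReplicateSet(f"1:{int(factor)}", values, "technical"))
    neg_mean = max(background, 1e-9 * base_signal)
    neg = ReplicateSet(
        "negative", neg_mean * _lognormal_factor(rng, cvs[-1], n_replicates), "technical"
    )
    series = DilutionSeries(factors, sets, neg)
    return series, {"base_signal": base_signal, "background": background}


@dataclasses.dataclass
class CtSimConfig:
    """Configuration of a synthetic qPCR experiment.

    ``true_folds`` maps (gene, condition) to the planted fold change versus
    the control condition; ``baseline_dct`` is each gene's expression offset
    (in cycles) above the reference gene in the control state.  Technical
    noise is per Ct measurement; biological noise shifts whole samples.
    Defaults match a routine validation qPCR: technical duplicates,
    3 biological replicates, 0.2-cycle technical noise.
    """

    genes: tuple[str, ...] = ("IL-6",)
    conditions: tuple[str, ...] = ("M0", "M1_DMSO")
    true_folds: dict[tuple[str, str], float] = dataclasses.field(default_factory=dict)
    baseline_dct: dict[str, float] = dataclasses.field(default_factory=dict)
    reference_gene: str = "RPL37A"
    reference_baseline_ct: float = 20.0
    control_condition: str = "M0"
    sigma_technical: float = 0.2
    sigma_biological: float = 0.0
    n_technical: int = 2
    n_biological: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_technical < 0 or self.sigma_biological < 0:
            raise ConfigError("noise SDs must be non-negative")
        if any(f <= 0 for f in self.true_folds.values()):
            raise ConfigError("true folds must be positive")


def simulate_ct_experiment(
    config: CtSimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, SimTruth]:
    """Generate a long-format Ct table with planted fold changes.

    Per (experiment, condition) the reference gene's latent Ct is its
    baseline plus biological noise; each target gene's latent Ct is the
    reference Ct plus the gene's baseline ΔCt minus log2 of the condition's
    true fold.  Technical replicates add independent technical noise to the
    latent values.  With all noise at zero, the expression module recovers
    the planted folds exactly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    truth = SimTruth()
    rows = []
    for b in range(1, config.n_biological + 1):
        exp_id = f"E{b}"
        for cond in config.conditions:
            ref_latent = config.reference_baseline_ct + (
                rng.normal(0.0, config.sigma_biological)
                if config.sigma_biological
                else 0.0
            )
            for _ in range(config.n_technical):
                rows.append(
                    {
                        "experiment_id": exp_id,
                        "condition": cond,
                        "gene": config.reference_gene,
                        "ct": ref_latent
                        + (
                            rng.normal(0.0, config.sigma_technical)
                            if config.sigma_technical
                            else 0.0
                        ),
                    }
                )
            for gene in config.genes:
                fold = (
                    1.0
                    if cond == config.control_condition
                    else config.true_folds.get((gene, cond), 1.0)
                )
                truth.true_folds[(gene, cond)] = fold
                base_dct = config.baseline_dct.get(gene, 5.0)
                latent = (
                    ref_latent
                    + base_dct
                    - math.log2(fold)
                    + (
                        rng.normal(0.0, config.sigma_biological)
                        if config.sigma_biological
                        else 0.0
                    )
                )
                for _ in range(config.n_technical):
                    rows.append(
                        {
                            "experiment_id": exp_id,
                            "condition": cond,
                            "gene": gene,
                            "ct": latent
                            + (
                                rng.normal(0.0, config.sigma_technical)
                                if config.sigma_technical
                                else 0.0
                            ),
                        }
                    )
    return pd.DataFrame(rows), truth
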