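"""Synthetic flow-cytometry dataset generator with truth manifests.

Produces complete, deterministic characterization datasets — event-level
fluorescence with scatter channels, autofluorescence and RPU-standard
controls — whose condition medians follow the mechanistic TES model.
Every generated dataset carries a :class:`TruthManifest` recording the
noise-free model outputs, the replicate perturbations, and the true Hill
parameters per tuner level, so the full analysis pipeline (gating,
correction, RPU conversion, Hill fitting, device metrics) can be tested
end to end without any external data.

Event model: fluorescence is log-normal around the condition median
(``median * exp(N(0, log_sd))``, so the distribution median is exact);
the condition median composes additively as ``signal + autofluorescence``.
Scatter channels come from a two-component Gaussian mixture in asinh
space (a dominant cell population plus a debris-like minor cluster) with
per-event cluster labels retained for gating-purity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from tunedev.cytometry_stats import EventSample
from tunedev.kinetic_model import (
    CHARACTERIZATION,
    GateParameters,
    TESParameters,
    not_gate_response,
    rpu_to_rnap,
    steady_state,
)
from tunedev.response_fitting import (
    HillFit,
    ResponseCurve,
    fit_hill_activation,
    fit_hill_repression,
)

__all__ = [
    "TUNER_GRID_RPU",
    "TES_INPUT_GRID_RPU",
    "NOT_INPUT_GRID_RPU",
    "NOR_INPUT_A_RPU",
    "NOR_INPUT_B_RPU",
    "NOR_TUNER_GRID_RPU",
    "DESIGNS",
    "SyntheticDatasetSpec",
    "ConditionRecord",
    "TruthManifest",
    "SyntheticDataset",
    "generate_events",
    "generate_device_dataset",
    "generate_nor_dataset",
]


#: Tuner-promoter activity grid (RPU) used for device characterization.
TUNER_GRID_RPU = (0.002, 0.03, 0.15, 0.43, 0.9, 2.6)
#: Input-promoter activity grid (RPU) for the bare TES (inducible sensor span).
TES_INPUT_GRID_RPU = (0.002, 0.03, 0.15, 0.9, 2.6, 6.6)
#: Input grid (RPU) for the NOT gate (narrower sensor).
NOT_INPUT_GRID_RPU = (0.002, 0.03, 0.15, 0.43, 0.9, 1.5)
#: NOR-gate input grids (RPU), one per input promoter.
NOR_INPUT_A_RPU = (0.008, 0.003, 0.15, 0.5, 2.5, 3.1)
NOR_INPUT_B_RPU = (0.05, 0.5, 1.6, 3.1, 6.4, 7.5)
#: Low/high tuner levels (RPU) for NOR-gate characterization.
NOR_TUNER_GRID_RPU = (0.002, 2.6)

#: Device design variants and how they modify the base parameters:
#: ``booster`` adds a high-copy sRNA booster plasmid (tuner transcription
#: x ``booster_factor``); ``noninsulated`` removes the transcriptional
#: insulator upstream of the switch, adding constant read-through flux to
#: the input; ``combined`` applies both.
DESIGNS = ("original", "booster", "noninsulated", "combined")

_DEVICES = ("tes", "not", "nor")

# Scatter-mixture geometry (asinh-transformed channel units, cofactor 150):
# a dominant cell cluster and a well-separated debris-like minor cluster.
_SCATTER_MAIN_CENTER = (6.5, 6.0)
_SCATTER_MINOR_CENTER = (4.0, 3.5)
_SCATTER_SD = 0.35
_SCATTER_COFACTOR = 150.0
_MAIN_FRACTION = 0.85


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Full description of one synthetic characterization experiment.

    Grids are promoter activities in RPU.  ``replicate_cv`` is the
    multiplicative between-replicate coefficient of variation applied to
    the true signal median; ``log_sd`` is the event-level log-scale SD.
    ``gain`` converts model protein copies to fluorescence a.u.;
    ``rpu_standard_median`` is the true (autofluorescence-corrected)
    median of the 1-RPU standard strain in a.u.  The same spec + seed
    always regenerates the identical dataset and manifest.
    """

    device: str = "tes"
    design: str = "original"
    params: TESParameters = CHARACTERIZATION
    gate: GateParameters = field(default_factory=GateParameters)
    input_grid: tuple = TES_INPUT_GRID_RPU
    input_grid_b: tuple = NOR_INPUT_B_RPU
    tuner_grid: tuple = TUNER_GRID_RPU
    replicates: int = 3
    n_events: int = 100_000
    replicate_cv: float = 0.10
    log_sd: float = 0.45
    autofluorescence_median: float = 3.0
    rpu_standard_median: float = 42300.0
    gain: float = 1.0
    booster_factor: float = 5.0
    readthrough_flux: float = 0.5
    include_scatter: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.device not in _DEVICES:
            raise ValueError(f"device must be one of {_DEVICES}, got {self.device!r}")
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}, got {self.design!r}")
        for name in ("input_grid", "input_grid_b", "tuner_grid"):
            grid = tuple(float(v) for v in getattr(self, name))
            if len(grid) == 0 or any(v <= 0 for v in grid):
                raise ValueError(f"{name} must be non-empty with positive RPU values")
            object.__setattr__(self, name, grid)
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if self.n_events < 1:
            raise ValueError(f"n_events must be >= 1, got {self.n_events}")
        if self.replicate_cv < 0 or self.log_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.autofluorescence_median <= 0:
            raise ValueError("autofluorescence_median must be > 0")
        if self.rpu_standard_median <= 0 or self.gain <= 0:
            raise ValueError("rpu_standard_median and gain must be > 0")
        if self.booster_factor < 1 or self.readthrough_flux < 0:
            raise ValueError("booster_factor must be >= 1 and readthrough_flux >= 0")


@dataclass(frozen=True)
class ConditionRecord:
    """Ground truth for one generated (condition x replicate) sample."""

    device: str
    design: str
    tuner_rpu: float
    replicate: int
    input_rpu: float | None = None
    input_a_rpu: float | None = None
    input_b_rpu: float | None = None
    true_signal_median: float = 0.0  # a.u., noise-free model output x gain
    true_output_rpu: float = 0.0  # true_signal_median / rpu_standard_median
    replicate_factor: float = 1.0
    event_median: float = 0.0  # a.u., replicate-perturbed signal + autofluorescence
    n_events: int = 0
    child_seed: int = 0

    @property
    def key(self) -> tuple:
        if self.device == "nor":
            return (self.input_a_rpu, self.input_b_rpu, self.tuner_rpu, self.replicate)
        return (self.input_rpu, self.tuner_rpu, self.replicate)


@dataclass(frozen=True)
class TruthManifest:
    """Everything the generator knew: per-condition truths plus fit targets.

    ``hill_truth`` maps tuner RPU to the Hill fit of the *noise-free*
    model medians over the input grid (the identifiability target for
    parameter-recovery tests); it is ``None`` for NOR datasets, whose
    truth is the full 2-D output grid in ``conditions``.
    ``cluster_labels`` maps each sample key (and control names) to the
    per-event scatter-cluster label array (1 = dominant population).
    """

    conditions: tuple
    hill_truth: Mapping[float, HillFit] | None
    cluster_labels: Mapping[tuple | str, np.ndarray]
    autofluorescence_median: float
    rpu_standard_median: float
    seed: int


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated samples plus controls and the truth manifest."""

    spec: SyntheticDatasetSpec
    samples: Mapping[tuple, EventSample]
    autofluorescence_controls: tuple
    rpu_standards: tuple
    manifest: TruthManifest

    def to_frame(self) -> pd.DataFrame:
        """Long-format event table (one row per event, tidy columns).

        Device conditions carry ``sample = "device"``; the per-replicate
        controls appear with ``sample`` set to ``"autofluorescence_control"``
        or ``"rpu_standard"`` and NaN condition activities, so one table
        holds everything the analysis pipeline needs.
        """

        def block(s: EventSample, sample: str, labels_key, **meta) -> pd.DataFrame:
            n = s.n_events
            cols = {"sample": np.full(n, sample), "device": np.full(n, self.spec.device),
                    "design": np.full(n, self.spec.design)}
            for k, v in meta.items():
                cols[k] = np.full(n, v)
            cols["yfp"] = s.yfp
            if s.fsc is not None:
                cols["fsc"] = s.fsc
                cols["ssc"] = s.ssc
                cols["cluster_label"] = self.manifest.cluster_labels[labels_key]
            return pd.DataFrame(cols)

        frames = []
        for rec in self.manifest.conditions:
            meta = {"tuner_rpu": rec.tuner_rpu, "replicate": rec.replicate}
            if rec.device == "nor":
                meta.update(input_a_rpu=rec.input_a_rpu, input_b_rpu=rec.input_b_rpu)
            else:
                meta.update(input_rpu=rec.input_rpu)
            frames.append(block(self.samples[rec.key], "device", rec.key, **meta))
        for name, group in (
            ("autofluorescence_control", self.autofluorescence_controls),
            ("rpu_standard", self.rpu_standards),
        ):
            for rep, s in enumerate(group):
                frames.append(block(s, name, (name, rep), replicate=rep))
        return pd.concat(frames, ignore_index=True)


def generate_events(
    median: float,
    log_sd: float,
    n: int,
    seed: int,
    condition: Mapping[str, object] | None = None,
    include_scatter: bool = True,
    main_fraction: float = _MAIN_FRACTION,
) -> tuple[EventSample, np.ndarray]:
    """Draw one event sample; returns ``(sample, cluster_labels)``.

    Fluorescence is ``median * exp(N(0, log_sd))``, so the distribution
    median equals ``median`` exactly and ``log_sd = 0`` collapses every
    event onto it.  Scatter channels are a two-component Gaussian mixture
    in asinh space; ``cluster_labels`` is 1 for the dominant population
    and 0 for the minor one (an empty array when scatter is disabled).
    The same arguments always reproduce the identical sample.
    """
    if n < 1:
        raise ValueError(f"need n >= 1 events, got {n}")
    if median <= 0:
        raise ValueError(f"median must be > 0, got {median}")
    if log_sd < 0:
        raise ValueError(f"log_sd must be >= 0, got {log_sd}")
    if not 0 < main_fraction <= 1:
        raise ValueError(f"main_fraction must be in (0, 1], got {main_fraction}")
    rng = np.random.default_rng(seed)
    yfp = median * np.exp(rng.normal(0.0, log_sd, n)) if log_sd > 0 else np.full(n, float(median))
    if not include_scatter:
        return EventSample(yfp=yfp, condition=condition), np.empty(0, dtype=np.int64)
    labels = (rng.random(n) < main_fraction).astype(np.int64)
    cx = np.where(labels == 1, _SCATTER_MAIN_CENTER[0], _SCATTER_MINOR_CENTER[0])
    cy = np.where(labels == 1, _SCATTER_MAIN_CENTER[1], _SCATTER_MINOR_CENTER[1])
    fsc = _SCATTER_COFACTOR * np.sinh(cx + rng.normal(0.0, _SCATTER_SD, n))
    ssc = _SCATTER_COFACTOR * np.sinh(cy + rng.normal(0.0, _SCATTER_SD, n))
    sample = EventSample(
        yfp=yfp, fsc=fsc, ssc=ssc, condition=condition, source_index=np.arange(n)
    )
    return sample, labels


def _design_params(spec: SyntheticDatasetSpec, u_in_rnap: float, u_tun_rnap: float) -> TESParameters:
    """Apply the design variant and the RPU-bridged promoter activities."""
    kw = {"u_in": u_in_rnap, "u_tun": u_tun_rnap}
    if spec.design in ("booster", "combined"):
        kw["booster_factor"] = spec.booster_factor
    if spec.design in ("noninsulated", "combined"):
        kw["u_in"] = u_in_rnap + spec.readthrough_flux
    return replace(spec.params, **kw)


def _true_signal_median(spec: SyntheticDatasetSpec, input_rpu: float, tuner_rpu: float) -> float:
    """Noise-free fluorescence signal median (a.u.) for one condition."""
    p = _design_params(spec, rpu_to_rnap(input_rpu), rpu_to_rnap(tuner_rpu))
    try:
        if spec.device == "tes":
            return spec.gain * steady_state(p).p
        # NOT gate: the reporter sits on the repressed output promoter and is
        # measured against the same standard, so output RPU scales directly.
        out_rpu = not_gate_response(p, spec.gate)
        return out_rpu * spec.rpu_standard_median
    except Exception as err:
        raise RuntimeError(
            f"model evaluation failed at input={input_rpu} RPU, "
            f"tuner={tuner_rpu} RPU, design={spec.design!r}: {err}"
        ) from err


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Independent 31-bit child seeds from one root seed."""
    states = [s.generate_state(1)[0] for s in np.random.SeedSequence(seed).spawn(n)]
    return np.asarray(states, dtype=np.int64) & 0x7FFFFFFF


def _replicate_factors(spec: SyntheticDatasetSpec, rng: np.random.Generator) -> np.ndarray:
    """One multiplicative factor per biological replicate (batch effect).

    Replicate noise models day-to-day variation of a culture measured
    across the whole condition grid, so the factor is shared by every
    condition within a replicate rather than redrawn per condition.
    """
    if spec.replicate_cv == 0:
        return np.ones(spec.replicates)
    sigma = np.sqrt(np.log1p(spec.replicate_cv**2))
    return np.exp(rng.normal(0.0, sigma, spec.replicates))


def _controls(
    spec: SyntheticDatasetSpec,
    seeds: np.ndarray,
    labels: dict,
) -> tuple[tuple, tuple]:
    """Autofluorescence-control and RPU-standard samples, one per replicate."""
    af, std = [], []
    for rep in range(spec.replicates):
        s, lab = generate_events(
            spec.autofluorescence_median, spec.log_sd, spec.n_events, int(seeds[2 * rep]),
            condition={"sample": "autofluorescence_control", "replicate": rep},
            include_scatter=spec.include_scatter,
        )
        labels[("autofluorescence_control", rep)] = lab
        af.append(s)
        s, lab = generate_events(
            spec.rpu_standard_median + spec.autofluorescence_median,
            spec.log_sd, spec.n_events, int(seeds[2 * rep + 1]),
            condition={"sample": "rpu_standard", "replicate": rep},
            include_scatter=spec.include_scatter,
        )
        labels[("rpu_standard", rep)] = lab
        std.append(s)
    return tuple(af), tuple(std)


def generate_device_dataset(spec: SyntheticDatasetSpec) -> SyntheticDataset:
    """Generate a full TES or NOT-gate characterization dataset.

    One event sample per (input x tuner x replicate) condition, whose
    true signal median is the mechanistic model output (scaled to a.u.)
    perturbed by multiplicative replicate noise; plus per-replicate
    autofluorescence-control and RPU-standard samples.  The manifest
    records every truth, including the Hill parameters of the noise-free
    response per tuner level.
    """
    if spec.device not in ("tes", "not"):
        raise ValueError(f"generate_device_dataset handles tes/not, got {spec.device!r}")
    conditions = [
        (ui, ut, rep)
        for ut in spec.tuner_grid
        for ui in spec.input_grid
        for rep in range(spec.replicates)
    ]
    seeds = _child_seeds(spec.seed, len(conditions) + 2 * spec.replicates + 1)
    rep_rng = np.random.default_rng(int(seeds[-1]))
    factors = _replicate_factors(spec, rep_rng)

    truths = {
        (ui, ut): _true_signal_median(spec, ui, ut)
        for ut in spec.tuner_grid
        for ui in spec.input_grid
    }
    fit = fit_hill_activation if spec.device == "tes" else fit_hill_repression
    hill_truth = {
        ut: fit(ResponseCurve(
            np.asarray(spec.input_grid),
            np.asarray([truths[(ui, ut)] for ui in spec.input_grid]),
            tuner_activity=ut, design=spec.design,
        ))
        for ut in spec.tuner_grid
    }

    samples, labels, records = {}, {}, []
    for i, (ui, ut, rep) in enumerate(conditions):
        true_med = truths[(ui, ut)]
        event_med = true_med * factors[rep] + spec.autofluorescence_median
        cond_meta = {
            "device": spec.device, "design": spec.design,
            "input_rpu": ui, "tuner_rpu": ut, "replicate": rep,
        }
        sample, lab = generate_events(
            event_med, spec.log_sd, spec.n_events, int(seeds[i]),
            condition=cond_meta, include_scatter=spec.include_scatter,
        )
        rec = ConditionRecord(
            device=spec.device, design=spec.design, tuner_rpu=ut, replicate=rep,
            input_rpu=ui, true_signal_median=true_med,
            true_output_rpu=true_med / spec.rpu_standard_median,
            replicate_factor=float(factors[rep]), event_median=event_med,
            n_events=spec.n_events, child_seed=int(seeds[i]),
        )
        samples[rec.key] = sample
        labels[rec.key] = lab
        records.append(rec)

    af, std = _controls(spec, seeds[len(conditions):], labels)
    manifest = TruthManifest(
        conditions=tuple(records), hill_truth=hill_truth, cluster_labels=labels,
        autofluorescence_median=spec.autofluorescence_median,
        rpu_standard_median=spec.rpu_standard_median, seed=spec.seed,
    )
    return SyntheticDataset(
        spec=spec, samples=samples, autofluorescence_controls=af,
        rpu_standards=std, manifest=manifest,
    )


def generate_nor_dataset(spec: SyntheticDatasetSpec) -> SyntheticDataset:
    """Generate a NOR-gate dataset over the (input A x input B) grid.

    ``spec.input_grid`` is the input-A grid and ``spec.input_grid_b`` the
    input-B grid; each (a, b, tuner, replicate) condition's true median
    follows the NOR response (output RPU x standard median).  The gate is
    symmetric in its inputs, so transposing which promoter is called A
    transposes the output grid exactly.
    """
    if spec.device != "nor":
        raise ValueError(f"generate_nor_dataset requires device='nor', got {spec.device!r}")
    conditions = [
        (ua, ub, ut, rep)
        for ut in spec.tuner_grid
        for ua in spec.input_grid
        for ub in spec.input_grid_b
        for rep in range(spec.replicates)
    ]
    seeds = _child_seeds(spec.seed, len(conditions) + 2 * spec.replicates + 1)
    rep_rng = np.random.default_rng(int(seeds[-1]))
    factors = _replicate_factors(spec, rep_rng)

    samples, labels, records = {}, {}, []
    for i, (ua, ub, ut, rep) in enumerate(conditions):
        p = _design_params(spec, rpu_to_rnap(ua) + rpu_to_rnap(ub), rpu_to_rnap(ut))
        try:
            out_rpu = not_gate_response(p, spec.gate)
        except Exception as err:
            raise RuntimeError(
                f"model evaluation failed at input_a={ua} RPU, input_b={ub} RPU, "
                f"tuner={ut} RPU, design={spec.design!r}: {err}"
            ) from err
        true_med = out_rpu * spec.rpu_standard_median
        event_med = true_med * factors[rep] + spec.autofluorescence_median
        cond_meta = {
            "device": "nor", "design": spec.design,
            "input_a_rpu": ua, "input_b_rpu": ub, "tuner_rpu": ut, "replicate": rep,
        }
        sample, lab = generate_events(
            event_med, spec.log_sd, spec.n_events, int(seeds[i]),
            condition=cond_meta, include_scatter=spec.include_scatter,
        )
        rec = ConditionRecord(
            device="nor", design=spec.design, tuner_rpu=ut, replicate=rep,
            input_a_rpu=ua, input_b_rpu=ub, true_signal_median=true_med,
            true_output_rpu=out_rpu, replicate_factor=float(factors[rep]),
            event_median=event_med, n_events=spec.n_events, child_seed=int(seeds[i]),
        )
        samples[rec.key] = sample
        labels[rec.key] = lab
        records.append(rec)

    af, std = _controls(spec, seeds[len(conditions):], labels)
    manifest = TruthManifest(
        conditions=tuple(records), hill_truth=None, cluster_labels=labels,
        autofluorescence_median=spec.autofluorescence_median,
        rpu_standard_median=spec.rpu_standard_median, seed=spec.seed,
    )
    return SyntheticDataset(
        spec=spec, samples=samples, autofluorescence_controls=af,
        rpu_standards=std, manifest=manifest,
    )
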