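"""Discrete-event compartmental mass-balance simulation of a digestion run.

A run is an :class:`EventTimeline` — feed pulses, fluid additions, sampling
withdrawals, pyloric pulses with matched intestinal fluid, and terminal
drains — executed over three well-mixed compartments (oral, gastric,
intestinal).  Starch hydrolysis is first order per compartment, so the state
between events has a closed form (no numerical integrator is involved):

    S(t0 + dt) = S(t0) * exp(-k * dt)
    G(t0 + dt) = G(t0) + yield * S(t0) * (1 - exp(-k * dt))

where ``yield`` = 1/0.9 accounts for the water added on hydrolysis (1 g of
anhydroglucose yields ~1.11 g of free glucose).  Salivary amylase is
inactivated on gastric entry, which together with the default
``k_gastric = 0`` reproduces the observed flat gastric starch trend.  A
non-starch glucogenic pool (fermentation saccharides) converts to glucose in
the intestinal compartment only.

Events move volume and concentration-proportional mass; sampling records the
withdrawn aliquot's masses.  The simulator is deterministic; measurement
noise belongs to :mod:`midasim.synthetic`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .emptying import PulseSchedule
from .errors import ConfigurationError, DomainError, InfeasiblePlanError, MidaError
from .protocol import FoodSpec, SamplingPlan, VolumePlan

__all__ = [
    "KineticParams",
    "Event",
    "EventTimeline",
    "SimTimeSeries",
    "FitResult",
    "build_timeline",
    "simulate",
    "fit_first_order_kinetics",
    "GLUCOSE_YIELD_DEFAULT",
]

#: Mass of free D-glucose produced per mass of starch hydrolyzed (the
#: reciprocal of the 0.9 anhydroglucose stoichiometric constant).
GLUCOSE_YIELD_DEFAULT = 1.0 / 0.9

_EVENT_PRIORITY = {
    "phase_change": 0,
    "add_food": 1,
    "add_fluid": 2,
    "feed_pulse": 3,
    "pyloric_pulse": 4,
    "sample": 5,
}

SAMPLE_COLUMNS = ["time_min", "compartment", "purpose", "sample_volume_ml",
                  "starch_g", "glucose_g", "replicate"]


@dataclass(frozen=True)
class KineticParams:
    """First-order hydrolysis rates per compartment (per minute)."""

    k_oral: float
    k_intestinal: float
    k_gastric: float = 0.0
    glucose_yield: float = GLUCOSE_YIELD_DEFAULT
    glucogenic_rate: float | None = None  # None -> same as k_intestinal

    def __post_init__(self) -> None:
        for fld in ("k_oral", "k_intestinal", "k_gastric"):
            if getattr(self, fld) < 0:
                raise DomainError(f"{fld} must be >= 0")
        if self.glucose_yield <= 0:
            raise DomainError("glucose_yield must be > 0")
        if self.glucogenic_rate is not None and self.glucogenic_rate < 0:
            raise DomainError("glucogenic_rate must be >= 0")

    @property
    def effective_glucogenic_rate(self) -> float:
        return self.k_intestinal if self.glucogenic_rate is None else self.glucogenic_rate

    def starch_rate(self, compartment: str) -> float:
        return {"oral": self.k_oral, "gastric": self.k_gastric,
                "intestinal": self.k_intestinal}[compartment]

    def to_dict(self) -> dict:
        return {
            "k_oral": self.k_oral,
            "k_intestinal": self.k_intestinal,
            "k_gastric": self.k_gastric,
            "glucose_yield": self.glucose_yield,
            "glucogenic_rate": self.glucogenic_rate,
        }


@dataclass(frozen=True)
class Event:
    time_min: float
    kind: str
    compartment: str
    volume_ml: float
    label: str = ""
    purpose: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _EVENT_PRIORITY:
            raise ConfigurationError(f"unknown event kind {self.kind!r}")
        if self.volume_ml < 0:
            raise DomainError("event volume must be >= 0")


@dataclass(frozen=True)
class EventTimeline:
    """Time-ordered events of one run; equal-time events execute inflows first."""

    events: tuple[Event, ...]

    def __post_init__(self) -> None:
        ordered = tuple(sorted(
            self.events, key=lambda e: (e.time_min, _EVENT_PRIORITY[e.kind])
        ))
        object.__setattr__(self, "events", ordered)

    @property
    def n_sample_events(self) -> int:
        return sum(1 for e in self.events if e.kind == "sample")

    def count(self, kind: str | None = None, purpose: str | None = None) -> int:
        return sum(
            1 for e in self.events
            if (kind is None or e.kind == kind) and (purpose is None or e.purpose == purpose)
        )

    @property
    def horizon_min(self) -> float:
        return self.events[-1].time_min if self.events else 0.0


def build_timeline(
    food: FoodSpec,
    volume_plan: VolumePlan,
    sampling_plan: SamplingPlan,
    schedule: PulseSchedule,
    *,
    oral_end_min: float = 2.0,
    feed_interval_min: float = 2.0,
    feed_bolus_ml: float = 10.0,
    gastric_end_min: float = 122.0,
) -> EventTimeline:
    """Assemble the event timeline of a standard run.

    Oral phase 0-2 min (portion mixed 50:50 with SSF); gastric feeding of
    ``feed_bolus_ml`` bolus + equal SGF every ``feed_interval_min`` starting
    at the end of the oral hold; gastric phase to ``gastric_end_min``;
    pyloric pulses with matched SIF per ``schedule`` from there; sampling
    withdrawals per ``sampling_plan``.
    """
    n_feeds_f = volume_plan.gastric_food_input_ml / feed_bolus_ml
    n_feeds = round(n_feeds_f)
    if abs(n_feeds_f - n_feeds) > 1e-9:
        raise ConfigurationError(
            f"gastric food input {volume_plan.gastric_food_input_ml} ml is not a "
            f"whole number of {feed_bolus_ml}-ml boluses"
        )
    events = [
        Event(0.0, "add_food", "oral", food.portion_volume_ml, label="food"),
        Event(0.0, "add_fluid", "oral", volume_plan.ssf_ml, label="SSF"),
        # every bolus is held 2 min at 37C; tubes awaiting gastric entry are
        # modelled as identical to the first, so oral hydrolysis stops here
        Event(oral_end_min, "phase_change", "oral", 0.0, label="oral hold ends"),
        Event(gastric_end_min, "phase_change", "intestinal", 0.0, label="intestinal phase"),
    ]
    for i in range(n_feeds):
        t = oral_end_min + i * feed_interval_min
        events.append(Event(t, "feed_pulse", "gastric", feed_bolus_ml, label="bolus"))
        events.append(Event(t, "add_fluid", "gastric", feed_bolus_ml, label="SGF"))
    for t, v in schedule.pulse_times_and_volumes(offset_min=gastric_end_min):
        events.append(Event(t, "pyloric_pulse", "intestinal", v, label="chyme"))
        events.append(Event(t, "add_fluid", "intestinal", v, label="SIF"))
    for s in sampling_plan.events:
        events.append(Event(s.time_min, "sample", s.compartment, s.sample_volume_ml,
                            purpose=s.purpose))
    return EventTimeline(events=tuple(events))


@dataclass
class SimTimeSeries:
    """Sampled (time, compartment, starch, glucose) records plus run metadata."""

    samples: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    final_state: dict | None = None
    ledger: dict | None = None

    @property
    def replicates(self) -> list[int]:
        return sorted(self.samples["replicate"].unique().tolist())

    def to_csv(self, path: str | Path, metadata_sidecar: bool = True) -> None:
        path = Path(path)
        self.samples.to_csv(path, index=False)
        if metadata_sidecar and self.metadata is not None:
            path.with_suffix(path.suffix + ".meta.json").write_text(
                json.dumps(self.metadata, indent=2, default=str), encoding="utf-8"
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "SimTimeSeries":
        path = Path(path)
        df = pd.read_csv(path)
        missing = [c for c in SAMPLE_COLUMNS if c not in df.columns and c != "purpose"]
        if missing:
            raise MidaError(f"{path}: missing columns {missing}")
        if "purpose" not in df.columns:
            df["purpose"] = df["compartment"]
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        metadata = json.loads(meta_path.read_text(encoding="utf-8")) if meta_path.exists() else {}
        return cls(samples=df[SAMPLE_COLUMNS], metadata=metadata)


class _Compartment:
    __slots__ = ("volume", "starch", "glucose", "glucogenic")

    def __init__(self) -> None:
        self.volume = 0.0
        self.starch = 0.0
        self.glucose = 0.0
        self.glucogenic = 0.0

    def check(self, where: str) -> None:
        if min(self.volume, self.starch, self.glucose, self.glucogenic) < -1e-9:
            raise MidaError(f"internal invariant violation: negative state at {where}")
        # clamp float dust
        self.volume = max(self.volume, 0.0)
        self.starch = max(self.starch, 0.0)
        self.glucose = max(self.glucose, 0.0)
        self.glucogenic = max(self.glucogenic, 0.0)


def simulate(
    food: FoodSpec,
    timeline: EventTimeline,
    kinetics: KineticParams,
    sample_basis: str = "aliquot",
) -> SimTimeSeries:
    """Run the deterministic forward model over a timeline.

    Returns a :class:`SimTimeSeries` whose records hold the withdrawn
    aliquot's starch and glucose masses (``replicate`` = 0).  With
    ``sample_basis="compartment"`` the recorded masses are instead the whole
    compartment's contents just before the withdrawal (the withdrawal itself
    always removes the aliquot).  ``final_state`` and ``ledger`` carry the
    end-of-run compartment contents and the exact volume/mass bookkeeping
    used by the conservation checks.
    """
    if sample_basis not in ("aliquot", "compartment"):
        raise DomainError("sample_basis must be 'aliquot' or 'compartment'")
    comps = {c: _Compartment() for c in ("oral", "gastric", "intestinal")}
    ledger = {
        "volume_in_ml": 0.0,
        "volume_sampled_ml": 0.0,
        "baseline_volume_ml": 0.0,
        "starch_in_g": 0.0,
        "glucose_in_g": 0.0,
        "glucogenic_in_g": 0.0,
        "starch_consumed_g": 0.0,
        "glucose_produced_g": 0.0,
        "glucogenic_consumed_g": 0.0,
        "starch_sampled_g": 0.0,
        "glucose_sampled_g": 0.0,
        "glucogenic_sampled_g": 0.0,
        "pulse_volume_clipped_ml": 0.0,
    }
    g_rate = kinetics.effective_glucogenic_rate
    oral_active = True  # salivary amylase acts only during the oral hold

    def advance(dt: float) -> None:
        if dt <= 0:
            return
        for name, c in comps.items():
            k = kinetics.starch_rate(name)
            if name == "oral" and not oral_active:
                k = 0.0
            if k > 0 and c.starch > 0:
                consumed = c.starch * (1.0 - math.exp(-k * dt))
                c.starch -= consumed
                produced = kinetics.glucose_yield * consumed
                c.glucose += produced
                ledger["starch_consumed_g"] += consumed
                ledger["glucose_produced_g"] += produced
            if name == "intestinal" and g_rate > 0 and c.glucogenic > 0:
                consumed = c.glucogenic * (1.0 - math.exp(-g_rate * dt))
                c.glucogenic -= consumed
                produced = kinetics.glucose_yield * consumed
                c.glucose += produced
                ledger["glucogenic_consumed_g"] += consumed
                ledger["glucose_produced_g"] += produced

    def transfer(src: str, dst: str, v: float, t: float, clip: bool = False) -> None:
        s, d = comps[src], comps[dst]
        if v > s.volume + 1e-9:
            if not clip:
                raise InfeasiblePlanError(
                    f"transfer of {v} ml from {src} at t={t} min exceeds its "
                    f"{s.volume:.3f} ml content"
                )
            ledger["pulse_volume_clipped_ml"] += v - s.volume
            v = s.volume
        if s.volume <= 0:
            return
        frac = v / s.volume
        for attr in ("starch", "glucose", "glucogenic"):
            moved = getattr(s, attr) * frac
            setattr(s, attr, getattr(s, attr) - moved)
            setattr(d, attr, getattr(d, attr) + moved)
        s.volume -= v
        d.volume += v
        s.check(f"{src} after transfer at t={t}")

    records: list[dict] = []
    t_now = 0.0
    for ev in timeline.events:
        advance(ev.time_min - t_now)
        t_now = ev.time_min
        if ev.kind == "phase_change":
            if ev.compartment == "oral":
                oral_active = False
            continue
        if ev.kind == "add_food":
            c = comps[ev.compartment]
            c.volume += ev.volume_ml
            c.starch += food.starch_conc * ev.volume_ml
            c.glucose += food.glucose_conc * ev.volume_ml
            c.glucogenic += food.glucogenic_conc * ev.volume_ml
            ledger["volume_in_ml"] += ev.volume_ml
            ledger["starch_in_g"] += food.starch_conc * ev.volume_ml
            ledger["glucose_in_g"] += food.glucose_conc * ev.volume_ml
            ledger["glucogenic_in_g"] += food.glucogenic_conc * ev.volume_ml
        elif ev.kind == "add_fluid":
            comps[ev.compartment].volume += ev.volume_ml
            ledger["volume_in_ml"] += ev.volume_ml
        elif ev.kind == "feed_pulse":
            transfer("oral", ev.compartment, ev.volume_ml, t_now)
        elif ev.kind == "pyloric_pulse":
            transfer("gastric", ev.compartment, ev.volume_ml, t_now, clip=True)
        elif ev.kind == "sample":
            if ev.compartment == "food":
                # pre-digestion aliquot measured from the food stock itself
                records.append({
                    "time_min": t_now, "compartment": "food", "purpose": ev.purpose,
                    "sample_volume_ml": ev.volume_ml,
                    "starch_g": food.starch_conc * ev.volume_ml,
                    "glucose_g": food.glucose_conc * ev.volume_ml,
                    "replicate": 0,
                })
                ledger["baseline_volume_ml"] += ev.volume_ml
                continue
            c = comps[ev.compartment]
            if ev.volume_ml > c.volume + 1e-9:
                raise InfeasiblePlanError(
                    f"sample of {ev.volume_ml} ml from {ev.compartment} at "
                    f"t={t_now} min exceeds its {c.volume:.3f} ml content"
                )
            frac = ev.volume_ml / c.volume
            rec_s, rec_g = c.starch * frac, c.glucose * frac
            records.append({
                "time_min": t_now, "compartment": ev.compartment, "purpose": ev.purpose,
                "sample_volume_ml": ev.volume_ml,
                "starch_g": rec_s if sample_basis == "aliquot" else c.starch,
                "glucose_g": rec_g if sample_basis == "aliquot" else c.glucose,
                "replicate": 0,
            })
            c.starch -= rec_s
            c.glucose -= rec_g
            ledger["glucogenic_sampled_g"] += c.glucogenic * frac
            c.glucogenic -= c.glucogenic * frac
            c.volume -= ev.volume_ml
            ledger["volume_sampled_ml"] += ev.volume_ml
            ledger["starch_sampled_g"] += rec_s
            ledger["glucose_sampled_g"] += rec_g
            c.check(f"{ev.compartment} after sample at t={t_now}")

    samples = pd.DataFrame(records, columns=SAMPLE_COLUMNS)
    final_state = {
        name: {"volume_ml": c.volume, "starch_g": c.starch, "glucose_g": c.glucose,
               "glucogenic_g": c.glucogenic}
        for name, c in comps.items()
    }
    return SimTimeSeries(
        samples=samples,
        metadata={"food": food.name, "kinetics": kinetics.to_dict(),
                  "sample_basis": sample_basis, "seed": None},
        final_state=final_state,
        ledger=ledger,
    )


@dataclass(frozen=True)
class FitResult:
    """First-order rate recovered from log-linear decay of sampled starch."""

    rate_per_min: float
    ci_low: float
    ci_high: float
    per_replicate: dict[int, float]
    n_obs: int
    log_intercept: float


def fit_first_order_kinetics(
    ts: SimTimeSeries | pd.DataFrame,
    phase: str,
    t_range: tuple[float, float] | None = None,
    n_boot: int = 500,
    seed: int = 0,
) -> FitResult:
    """Least-squares fit of log starch concentration vs time within a phase.

    ``phase`` selects records by purpose (``"intestinal"`` includes the
    terminal drain samples).  ``t_range`` restricts to a window — for the
    intestinal phase, pass a window starting after the pyloric inflow ends so
    the decay is purely first order.  The confidence interval is a percentile
    bootstrap over replicates (normal-theory from the fit covariance when
    only one replicate is present).
    """
    df = ts.samples if isinstance(ts, SimTimeSeries) else ts
    purposes = {phase, "drain"} if phase == "intestinal" else {phase}
    sel = df[df["purpose"].isin(purposes)].copy()
    if t_range is not None:
        sel = sel[(sel["time_min"] >= t_range[0]) & (sel["time_min"] <= t_range[1])]
    sel["conc"] = sel["starch_g"] / sel["sample_volume_ml"]
    sel = sel[sel["conc"] > 0]
    if len(sel) == 0:
        raise MidaError(f"nothing to fit: no positive starch records in phase {phase!r}")
    if len(sel) < 3:
        raise MidaError(f"need at least 3 records to fit phase {phase!r}, got {len(sel)}")

    t = sel["time_min"].to_numpy(float)
    logc = np.log(sel["conc"].to_numpy(float))

    def _rate(tt: np.ndarray, yy: np.ndarray) -> tuple[float, float]:
        slope, intercept = np.polyfit(tt, yy, 1)
        return -slope, intercept

    rate, intercept = _rate(t, logc)
    reps = sel["replicate"].unique()
    per_rep = {}
    for r in reps:
        m = sel["replicate"] == r
        if m.sum() >= 2:
            per_rep[int(r)] = _rate(t[m.to_numpy()], logc[m.to_numpy()])[0]

    if len(reps) >= 2 and n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        groups = {int(r): (t[(sel["replicate"] == r).to_numpy()],
                           logc[(sel["replicate"] == r).to_numpy()]) for r in reps}
        keys = list(groups)
        for b in range(n_boot):
            pick = rng.choice(len(keys), size=len(keys), replace=True)
            tt = np.concatenate([groups[keys[i]][0] for i in pick])
            yy = np.concatenate([groups[keys[i]][1] for i in pick])
            boots[b] = _rate(tt, yy)[0]
        ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    else:
        if len(sel) > 2:
            coef, cov = np.polyfit(t, logc, 1, cov=True)
            se = math.sqrt(max(cov[0, 0], 0.0))
        else:
            se = 0.0
        ci_low, ci_high = rate - 1.96 * se, rate + 1.96 * se

    return FitResult(
        rate_per_min=float(rate),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        per_replicate=per_rep,
        n_obs=int(len(sel)),
        log_intercept=float(intercept),
    )
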