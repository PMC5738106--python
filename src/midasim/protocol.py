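"""Protocol planning: fluid volumes, simulated-fluid recipes and enzyme doses.

The in vitro protocol mixes each compartment's simulated fluid (SSF, SGF,
SIF) 50:50 (v/v) with the stream arriving from the previous compartment, so
the fluid volume to prepare at each stage equals the incoming volume *after*
sampling withdrawals.  :func:`plan_fluid_volumes` does that bookkeeping;
:func:`make_fluid_recipe` returns the tabulated fluid make-up per food class;
:func:`dose_pancrelipase` and :func:`glucoamylase_activity` implement the
enzyme-dose rules (weight-based lipase dosing with fixed capsule composition,
and the duodenal glucoamylase:amylase activity ratio of 0.11).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, NamedTuple

from .errors import DomainError, EnumerationError, InfeasiblePlanError

__all__ = [
    "FoodSpec",
    "EnzymeDose",
    "FluidRecipe",
    "VolumePlan",
    "SampleEvent",
    "SamplingPlan",
    "PancrelipaseDose",
    "plan_fluid_volumes",
    "make_fluid_recipe",
    "electrolyte_stock_recipe",
    "dose_pancrelipase",
    "glucoamylase_activity",
    "enzyme_stock_amount",
    "default_sampling_plan",
    "GLUCOAMYLASE_TO_AMYLASE_RATIO",
    "REPORTED_PROTEASE_UNITS",
    "STOCK_ACTIVITIES",
]

#: Duodenal glucoamylase : pancreatic alpha-amylase activity ratio measured in
#: adult and pediatric duodenal aspirates.
GLUCOAMYLASE_TO_AMYLASE_RATIO = 0.11

#: Protease units per meal printed in the original M.I.D.A. protocol for a
#: 7.695-kg infant.  Inconsistent with the stated capsule composition
#: (600 protease : 10000 lipase -> 461.7 U for a 7695-U lipase dose); kept as
#: a documented discrepancy, never silently substituted for the capsule-ratio
#: dose that :func:`dose_pancrelipase` returns.
REPORTED_PROTEASE_UNITS = 770.0

#: Activities of the enzyme stocks used to convert a target activity
#: (U per ml of final compartment content) into an amount of stock to add.
#: Pepsin stocks are specified as a 3200-4500 U/mg range; the midpoint is the
#: default.  Pancrelipase is dosed from 150-mg capsules of 10000 lipase units.
STOCK_ACTIVITIES = {
    "salivary alpha-amylase": (10000.0, "U/ml"),
    "pancreatic alpha-amylase": (10000.0, "U/ml"),
    "pepsin": (3850.0, "U/mg"),
    "glucoamylase": (1300.0, "U/g"),
    "pancrelipase": (10000.0 / 150.0, "lipase U/mg"),
}

_FLUIDS = ("SSF", "SGF", "SIF")
_FOOD_CLASSES = ("rice_starch", "rice_cream_basic", "rice_cream_premium")


def _load_data(name: str) -> dict:
    with resources.files("midasim.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoodSpec:
    """A test food entering the digestion protocol.

    Masses (``starch_g``, ``glucose_g``, ``glucogenic_pool_g``) are the
    amounts measured in a reference aliquot of ``aliquot_ml`` (default 10 ml)
    of the prepared food, which is the unit in which the protocol reports all
    per-sample masses.  ``glucogenic_pool_g`` holds non-starch
    glucose-yielding saccharides (e.g. maltodextrins produced by
    fermentation); it is what lets the starch-hydrolysis percentage of a
    fermented food exceed 100%.
    """

    name: str
    portion_volume_ml: float
    starch_g: float
    glucose_g: float
    initial_pH: float
    caloric_density_kcal_ml: float | None = None
    needs_pepsin: bool = False
    needs_pancrelipase: bool = False
    glucogenic_pool_g: float = 0.0
    aliquot_ml: float = 10.0

    def __post_init__(self) -> None:
        if self.portion_volume_ml <= 0:
            raise DomainError("portion_volume_ml must be > 0")
        if self.aliquot_ml <= 0:
            raise DomainError("aliquot_ml must be > 0")
        for fld in ("starch_g", "glucose_g", "glucogenic_pool_g"):
            if getattr(self, fld) < 0:
                raise DomainError(f"{fld} must be >= 0")
        if not 0 < self.initial_pH < 14:
            raise DomainError("initial_pH must lie in (0, 14)")

    # concentrations in g/ml of prepared food
    @property
    def starch_conc(self) -> float:
        return self.starch_g / self.aliquot_ml

    @property
    def glucose_conc(self) -> float:
        return self.glucose_g / self.aliquot_ml

    @property
    def glucogenic_conc(self) -> float:
        return self.glucogenic_pool_g / self.aliquot_ml


@dataclass(frozen=True)
class EnzymeDose:
    """One enzyme addition to a simulated fluid."""

    enzyme: str
    target_activity: float
    amount: float
    amount_unit: str  # "ml", "g" or "mg"
    activity_basis: str = "U/ml of compartment content"

    def __post_init__(self) -> None:
        if self.target_activity < 0:
            raise DomainError("target_activity must be >= 0")
        if self.amount < 0:
            raise DomainError("amount must be >= 0")


@dataclass(frozen=True)
class FluidRecipe:
    """Make-up of one simulated digestive fluid for one food class.

    ``electrolyte_stock_ml`` maps each electrolyte stock solution to the
    volume contributed to this fluid (the tabulated per-400-ml stock
    composition scaled to the amount of stock actually used).
    """

    compartment: str
    fluid_name: str
    electrolyte_stock_ml: dict[str, float]
    enzymes: tuple[EnzymeDose, ...]
    cacl2_ml: float
    hcl_1M_ml: float
    nahco3_1M_ml: float
    water_to_volume_ml: float
    target_pH: float
    food_class: str = ""

    def __post_init__(self) -> None:
        for fld in ("cacl2_ml", "hcl_1M_ml", "nahco3_1M_ml", "water_to_volume_ml"):
            if getattr(self, fld) < 0:
                raise DomainError(f"{fld} must be >= 0")
        if any(v < 0 for v in self.electrolyte_stock_ml.values()):
            raise DomainError("electrolyte stock volumes must be >= 0")
        if self.component_volume_ml > self.water_to_volume_ml + 1e-9:
            raise DomainError(
                f"{self.fluid_name}: component volumes "
                f"({self.component_volume_ml:.3f} ml) exceed the final volume "
                f"({self.water_to_volume_ml} ml)"
            )

    @property
    def electrolyte_total_ml(self) -> float:
        return sum(self.electrolyte_stock_ml.values())

    @property
    def component_volume_ml(self) -> float:
        """Total volume of everything except make-up water (ml amounts only)."""
        vol = self.electrolyte_total_ml + self.cacl2_ml + self.hcl_1M_ml + self.nahco3_1M_ml
        vol += sum(d.amount for d in self.enzymes if d.amount_unit == "ml")
        return vol

    def to_rows(self) -> list[dict]:
        """Flat one-row-per-component view (fluid, component, amount, unit)."""
        rows = [
            {"fluid": self.fluid_name, "component": stock, "amount": v, "unit": "ml"}
            for stock, v in self.electrolyte_stock_ml.items()
        ]
        for d in self.enzymes:
            rows.append({"fluid": self.fluid_name, "component": d.enzyme,
                         "amount": d.amount, "unit": d.amount_unit})
        rows.append({"fluid": self.fluid_name, "component": "CaCl2 0.3 M",
                     "amount": self.cacl2_ml, "unit": "ml"})
        rows.append({"fluid": self.fluid_name, "component": "HCl 1 M",
                     "amount": self.hcl_1M_ml, "unit": "ml"})
        rows.append({"fluid": self.fluid_name, "component": "NaHCO3 1 M",
                     "amount": self.nahco3_1M_ml, "unit": "ml"})
        rows.append({"fluid": self.fluid_name, "component": "water to volume",
                     "amount": self.water_to_volume_ml, "unit": "ml"})
        return rows


@dataclass(frozen=True)
class VolumePlan:
    """Fluid volumes implied by the 50:50 mixing rule with sampling losses."""

    food_volume_ml: float
    ssf_ml: float
    gastric_food_input_ml: float
    sgf_ml: float
    gastric_total_ml: float
    gastric_sampled_ml: float
    chyme_delivered_ml: float
    sif_ml: float
    chyle_final_ml: float

    def __post_init__(self) -> None:
        for fld in self.__dataclass_fields__:
            if getattr(self, fld) < -1e-12:
                raise DomainError(f"{fld} must be >= 0")

    def to_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}


@dataclass(frozen=True)
class SampleEvent:
    time_min: float
    compartment: str
    sample_volume_ml: float
    purpose: str  # baseline | oral | gastric | intestinal | drain

    def __post_init__(self) -> None:
        if self.sample_volume_ml <= 0:
            raise DomainError("sample_volume_ml must be > 0")
        if self.purpose not in ("baseline", "oral", "gastric", "intestinal", "drain"):
            raise DomainError(f"unknown sample purpose {self.purpose!r}")


@dataclass(frozen=True)
class SamplingPlan:
    """Ordered withdrawal plan for one digestion run."""

    events: tuple[SampleEvent, ...]

    def __post_init__(self) -> None:
        times = [e.time_min for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise DomainError("sampling times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    def count(self, purpose: str) -> int:
        return sum(1 for e in self.events if e.purpose == purpose)


class PancrelipaseDose(NamedTuple):
    lipase_U: float
    amylase_U: float
    protease_U: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def plan_fluid_volumes(
    food_volume_ml: float,
    oral_sample_ml: float = 10.0,
    n_gastric_samples: int = 8,
    gastric_sample_ml: float = 10.0,
) -> VolumePlan:
    """Plan SSF/SGF/SIF volumes under the 50:50 rule with sampling losses.

    Each compartment's fluid matches the volume arriving from the previous
    compartment, after any aliquots withdrawn for analysis.  For the standard
    protocol (45-ml portion, one 10-ml oral bolus frozen, eight 10-ml gastric
    samples) this yields SSF 45 ml, SGF 80 ml, SIF 80 ml and a 160-ml final
    chyle.

    Raises
    ------
    InfeasiblePlanError
        If a sampling withdrawal exceeds the content available in its
        compartment.
    """
    if food_volume_ml < 0:
        raise DomainError("food_volume_ml must be >= 0")
    if oral_sample_ml < 0 or gastric_sample_ml < 0 or n_gastric_samples < 0:
        raise InfeasiblePlanError("infeasible sampling plan: negative sampling in oral or gastric compartment")

    ssf = food_volume_ml
    oral_total = food_volume_ml + ssf
    if oral_sample_ml > oral_total + 1e-12:
        raise InfeasiblePlanError(
            f"infeasible sampling plan in oral compartment: sample {oral_sample_ml} ml "
            f"exceeds {oral_total} ml of bolus"
        )
    gastric_food_input = oral_total - oral_sample_ml
    sgf = gastric_food_input
    gastric_total = gastric_food_input + sgf
    gastric_sampled = n_gastric_samples * gastric_sample_ml
    if gastric_sampled > gastric_total + 1e-12:
        raise InfeasiblePlanError(
            f"infeasible sampling plan in gastric compartment: {gastric_sampled} ml "
            f"sampled exceeds {gastric_total} ml of content"
        )
    chyme = gastric_total - gastric_sampled
    sif = chyme
    return VolumePlan(
        food_volume_ml=food_volume_ml,
        ssf_ml=ssf,
        gastric_food_input_ml=gastric_food_input,
        sgf_ml=sgf,
        gastric_total_ml=gastric_total,
        gastric_sampled_ml=gastric_sampled,
        chyme_delivered_ml=chyme,
        sif_ml=sif,
        chyle_final_ml=chyme + sif,
    )


def electrolyte_stock_recipe(fluid_name: str) -> dict[str, float]:
    """Tabulated electrolyte stock composition (ml per 400 ml of stock)."""
    data = _load_data("electrolyte_stocks.json")
    try:
        return dict(data["stocks"][fluid_name]["components_ml"])
    except KeyError:
        raise EnumerationError(
            f"unknown fluid {fluid_name!r}; expected one of {_FLUIDS}"
        ) from None


def make_fluid_recipe(fluid_name: str, food_class: str) -> FluidRecipe:
    """Return the tabulated recipe for one simulated fluid and food class.

    Recipes are stored as versioned data fixtures so that other
    INFOGEST-style recipes can be swapped in.  pH-adjustment volumes (HCl /
    NaHCO3) are tabulated per food class because they were determined by
    titration prior to digestion, not computed from buffer chemistry.
    """
    data = _load_data("fluid_recipes.json")
    if fluid_name not in _FLUIDS:
        raise EnumerationError(f"unknown fluid {fluid_name!r}; expected one of {_FLUIDS}")
    if food_class not in data["recipes"]:
        raise EnumerationError(
            f"unknown food class {food_class!r}; expected one of {_FOOD_CLASSES}"
        )
    entry = data["recipes"][food_class][fluid_name]
    stock = electrolyte_stock_recipe(fluid_name)
    stock_volume = _load_data("electrolyte_stocks.json")["stock_volume_ml"]
    scale = entry["electrolyte_stock_total_ml"] / stock_volume
    return FluidRecipe(
        compartment=data["fluid_compartment"][fluid_name],
        fluid_name=fluid_name,
        electrolyte_stock_ml={k: v * scale for k, v in stock.items()},
        enzymes=tuple(
            EnzymeDose(
                enzyme=e["enzyme"],
                target_activity=e["target_activity"],
                amount=e["amount"],
                amount_unit=e["amount_unit"],
                activity_basis=e["activity_basis"],
            )
            for e in entry["enzymes"]
        ),
        cacl2_ml=entry["cacl2_ml"],
        hcl_1M_ml=entry["hcl_1M_ml"],
        nahco3_1M_ml=entry["nahco3_1M_ml"],
        water_to_volume_ml=data["fluid_final_volume_ml"][fluid_name],
        target_pH=data["fluid_target_pH"][fluid_name],
        food_class=food_class,
    )


def dose_pancrelipase(
    weight_kg: float,
    lipase_units_per_kg: float = 1000.0,
    capsule_lipase: float = 10000.0,
    capsule_amylase: float = 8000.0,
    capsule_protease: float = 600.0,
) -> PancrelipaseDose:
    """Weight-based pancrelipase dose with amylase/protease scaled by capsule ratio.

    The lipase dose is ``weight_kg * lipase_units_per_kg`` (the Cystic
    Fibrosis Foundation meal-dosing rule); amylase and protease follow from
    the capsule composition.  Note the original protocol prints 770 protease
    units for a 7.695-kg infant, which contradicts its own capsule ratio
    (:data:`REPORTED_PROTEASE_UNITS`); this function always applies the ratio.
    """
    if weight_kg <= 0:
        raise DomainError("weight_kg must be > 0")
    if min(lipase_units_per_kg, capsule_lipase, capsule_amylase, capsule_protease) <= 0:
        raise DomainError("dose and capsule activities must be > 0")
    lipase = weight_kg * lipase_units_per_kg
    return PancrelipaseDose(
        lipase_U=lipase,
        amylase_U=lipase * capsule_amylase / capsule_lipase,
        protease_U=lipase * capsule_protease / capsule_lipase,
    )


def glucoamylase_activity(pancreatic_amylase_activity_U_per_ml: float) -> float:
    """Duodenal glucoamylase activity matched to pancreatic alpha-amylase (ratio 0.11)."""
    if pancreatic_amylase_activity_U_per_ml < 0:
        raise DomainError("activity must be >= 0")
    return GLUCOAMYLASE_TO_AMYLASE_RATIO * pancreatic_amylase_activity_U_per_ml


def enzyme_stock_amount(
    enzyme: str,
    target_U_per_ml: float,
    compartment_content_ml: float,
    stock_activity: float | None = None,
) -> float:
    """Amount of enzyme stock delivering a target activity per ml of content.

    ``compartment_content_ml`` is the volume over which the activity is
    defined — the *final* compartment content, i.e. twice the fluid volume
    under the 50:50 mixing rule.  The returned amount is in the stock's
    natural unit (ml for liquid stocks, g or mg for solids, per
    :data:`STOCK_ACTIVITIES`).
    """
    if target_U_per_ml < 0 or compartment_content_ml < 0:
        raise DomainError("activity and volume must be >= 0")
    if stock_activity is None:
        try:
            stock_activity = STOCK_ACTIVITIES[enzyme][0]
        except KeyError:
            raise EnumerationError(f"no stock activity known for enzyme {enzyme!r}") from None
    if stock_activity <= 0:
        raise DomainError("stock_activity must be > 0")
    return target_U_per_ml * compartment_content_ml / stock_activity


def default_sampling_plan(
    sample_volume_ml: float = 10.0,
    gastric_times: Iterable[float] = tuple(range(17, 123, 15)),
    intestinal_times: Iterable[float] = tuple(range(137, 243, 15)),
    drain_times: Iterable[float] = (244.0, 246.0, 248.0),
) -> SamplingPlan:
    """The 21-sample plan of the standard run.

    One pre-digestion baseline aliquot at t=0, the frozen oral bolus at t=2,
    eight gastric samples every 15 min (t=17..122), eight intestinal samples
    every 15 min (t=137..242), and three closely spaced drain samples
    (t=244, 246, 248) monitoring the emptying of the system — eleven
    intestinal-phase withdrawals in total.
    """
    events = [SampleEvent(0.0, "food", sample_volume_ml, "baseline"),
              SampleEvent(2.0, "oral", sample_volume_ml, "oral")]
    events += [SampleEvent(float(t), "gastric", sample_volume_ml, "gastric") for t in gastric_times]
    events += [SampleEvent(float(t), "intestinal", sample_volume_ml, "intestinal") for t in intestinal_times]
    events += [SampleEvent(float(t), "intestinal", sample_volume_ml, "drain") for t in drain_times]
    return SamplingPlan(events=tuple(events))
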