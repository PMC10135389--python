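"""Seeded synthetic cohorts emulating a fructose + STZ diabetes study.

Generates complete longitudinal datasets for a 2-arm design (control n=8,
induced n=16) over 7 protocol weeks: weekly body weights, cage-level food
and water accounting, glucometer readings with the 600 mg/dL ceiling,
forehead temperatures, 14-parameter welfare score sheets from three
observers, terminal morphometrics, and kidney weights.

The default calibration encodes the study conditions: induced animals
drink 10 % fructose during weeks 1-2, receive streptozotocin (40 mg/kg)
at the end of week 2, then develop hyperglycaemia, polyphagia,
polydipsia, a week-3 weight dip (81.25 % of induced animals lighter than
the week before) and a final-week dip (93.75 %), with welfare events
appearing after induction but the critical total of 4 almost never
reached.

Weight model
------------
Per animal the initial (week 1) and final (week 7) weights are drawn from
a bivariate normal matching the group means/SDs; intermediate weeks
interpolate between the two anchors along a group-level schedule plus a
group "shape" offset and small weekly jitter:

    w_k = w_1 + f_k * (w_7 - w_1) + b_k + e_k,   e_k ~ N(0, tau_k^2)

The offsets ``b_k`` at the dip weeks are solved in closed form so the
probability that an animal loses weight across the dip equals the
configured fraction.  Anchoring both ends lets the final coefficient of
variation differ freely from the initial one (the control group's final
CV is *smaller* than its initial CV, which a multiplicative random-walk
growth model cannot produce).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

from . import physiology_metrics as pm
from . import welfare_scoring as ws

__all__ = [
    "GroupWeightModel",
    "GlucoseWeekModel",
    "SimulationConfig",
    "CohortDataset",
    "default_config",
    "simulate_cohort",
    "recover_calibration",
    "expected_calibration",
]

WEEKS = tuple(range(1, 8))


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupWeightModel:
    """Anchored-interpolation weight trajectory for one group."""

    initial_mean: float
    initial_sd: float
    final_mean: float
    final_sd: float
    rho: float  # correlation between the initial and final anchors
    fractions: tuple[float, ...]  # f_1..f_7, f_1 = 0, f_7 = 1
    offsets: tuple[float, ...]  # b_1..b_7, b_1 = b_7 = 0
    jitter: tuple[float, ...]  # tau_1..tau_7 (g), tau_1 = tau_7 = 0

    def __post_init__(self) -> None:
        for name in ("fractions", "offsets", "jitter"):
            if len(getattr(self, name)) != len(WEEKS):
                raise ValueError(f"{name} must have one entry per week")
        if self.initial_sd < 0 or self.final_sd < 0 or any(t < 0 for t in self.jitter):
            raise ValueError("standard deviations must be non-negative")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("anchor correlation must be in (-1, 1)")

    def weekly_means(self) -> np.ndarray:
        d = self.final_mean - self.initial_mean
        return np.array(
            [self.initial_mean + f * d + b for f, b in zip(self.fractions, self.offsets)]
        )


@dataclass(frozen=True)
class GlucoseWeekModel:
    """Normal latent distributions for one measurement week, per state."""

    week: int
    fasted_mean: dict[str, float]
    fasted_sd: dict[str, float]
    fed_mean: dict[str, float]
    fed_sd: dict[str, float]
    # low responders: induced animals whose fed glycaemia stays below the
    # outlier region (< 250 mg/dL) instead of saturating the meter
    low_responder_fed_mean: float | None = None
    low_responder_fed_sd: float | None = None


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one synthetic cohort.

    Event probabilities are per induced animal and week; control animals
    show no welfare alterations under the default calibration.
    """

    n_control: int = 8
    n_induced: int = 16
    weeks: tuple[int, ...] = WEEKS
    animals_per_cage: int = 4
    fructose_pct: float = 10.0  # drinking-water fructose, weeks 1-2
    fructose_weeks: tuple[int, ...] = (1, 2)
    stz_dose_mg_per_kg: float = 40.0  # single i.p. dose, end of week 2
    stz_week: int = 2

    weight: Mapping[str, GroupWeightModel] = field(default_factory=dict)
    #: configured probability that an induced animal is lighter than the
    #: week before, across the two dip transitions (week 2->3, week 6->7)
    weight_loss_prob: Mapping[int, float] = field(default_factory=dict)

    #: g/animal/day group-week means and the cage-to-cage SD
    food_mean: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    food_sd: float = 1.0
    #: mL/animal/day group-week means and cage-to-cage SDs
    water_mean: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    water_sd: Mapping[str, float] = field(default_factory=dict)
    #: first week measured with the 24-h protocol instead of weekly bottles
    water_24h_from_week: int = 4

    glucose: tuple[GlucoseWeekModel, ...] = ()
    n_low_responders: int = 3

    temperature_mean: float = 36.0
    temperature_sd: float = 0.25

    #: parameter -> week -> level -> probability (induced animals)
    welfare_probs: Mapping[str, Mapping[int, Mapping[int, float]]] = field(
        default_factory=dict
    )
    observer_ids: tuple[str, ...] = ("obs1", "obs2", "obs3")
    observer_disagreement: float = 0.0

    #: terminal morphometrics: group -> (mean, sd)
    fasting_ratio: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    nal_cm: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    tc_cm: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    ap_cm: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    #: correlation of perimeter/length draws with the final weight z-score
    morpho_rho: float = 0.5

    #: kidney relative weights (g/kg): group -> organ -> (mean, sd)
    kidney_rel_weight: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_induced < 1:
            raise ValueError("group sizes must be >= 1")
        for wk, p in self.weight_loss_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"weight-loss probability for week {wk} outside [0,1]")
        for param, byweek in self.welfare_probs.items():
            for wk, levels in byweek.items():
                tot = sum(levels.values())
                if any(p < 0 for p in levels.values()) or tot > 1.0 + 1e-12:
                    raise ValueError(
                        f"welfare probabilities for {param} week {wk} invalid"
                    )


@dataclass
class CohortDataset:
    """Tidy longitudinal container for one simulated (or loaded) study."""

    animals: pd.DataFrame  # animal_id, group, cage_id
    weights: pd.DataFrame  # animal_id, week, grams, fasting
    consumption: pd.DataFrame  # cage-level food/water accounting
    glucose: pd.DataFrame  # animal_id, week, state, raw, value_mg_dl, censored
    temperatures: pd.DataFrame  # animal_id, week, celsius
    scores: pd.DataFrame  # animal_id, week, observer_id, parameter, level
    morphometrics: pd.DataFrame
    organs: pd.DataFrame
    config: SimulationConfig | None = None
    rubric: ws.RubricDefinition = field(default_factory=ws.default_rubric)


# --------------------------------------------------------------------------
# Closed-form calibration helpers
# --------------------------------------------------------------------------

def _dip_offset(
    target_p: float, df: float, mu_d: float, sd_d: float, tau_a: float, tau_b: float
) -> float:
    """Offset difference ``b_k - b_{k-1}`` making the probability of a
    week-on-week weight loss equal ``target_p`` under the anchored model.

    The weekly difference is ``df*(w7-w1) + db + e_k - e_{k-1}`` with
    ``w7-w1 ~ N(mu_d, sd_d^2)``, so the loss probability is a normal CDF
    and ``db`` has a closed form.
    """
    z = sps.norm.ppf(target_p)
    s = float(np.sqrt(df**2 * sd_d**2 + tau_a**2 + tau_b**2))
    return float(-z * s - df * mu_d)


def _loss_probability(model: GroupWeightModel, week: int) -> float:
    """Model-implied probability that an animal is lighter at ``week``
    than the week before."""
    i = week - 1  # index of `week` in the per-week tuples
    df = model.fractions[i] - model.fractions[i - 1]
    db = model.offsets[i] - model.offsets[i - 1]
    sd_d = float(
        np.sqrt(
            model.initial_sd**2
            + model.final_sd**2
            - 2 * model.rho * model.initial_sd * model.final_sd
        )
    )
    mu_d = model.final_mean - model.initial_mean
    s = float(
        np.sqrt(df**2 * sd_d**2 + model.jitter[i - 1] ** 2 + model.jitter[i] ** 2)
    )
    return float(sps.norm.cdf(-(df * mu_d + db) / s))


def _solve_censored_normal(
    censored_frac: float, censored_mean: float, ceiling: float = pm.GLUCOMETER_CEILING
) -> tuple[float, float]:
    """Parameters (mu, sigma) of a normal whose mass above ``ceiling``
    equals ``censored_frac`` and whose ceiling-censored mean equals
    ``censored_mean``."""
    z = sps.norm.ppf(censored_frac)  # mu = ceiling + z*sigma

    def gap(sigma: float) -> float:
        mu = ceiling + z * sigma
        a = (ceiling - mu) / sigma
        e_short = sigma * (a * sps.norm.cdf(a) + sps.norm.pdf(a))
        return (ceiling - e_short) - censored_mean

    sigma = brentq(gap, 1.0, 1000.0)
    return ceiling + z * sigma, float(sigma)


# --------------------------------------------------------------------------
# Default calibration
# --------------------------------------------------------------------------

def default_config() -> SimulationConfig:
    """Calibration constants of the emulated study.

    Weight anchors reproduce the printed group means/SDs (initial
    130.57 +/- 12.29 control, 133.75 +/- 10.92 induced; final
    349.33 +/- 21.76, 256.07 +/- 51.99).  The induced dip offsets are
    solved so that 81.25 % of induced animals lose weight into week 3 and
    93.75 % into week 7.  Fed induced glycaemia at week 4 is a normal
    whose 600-censored mean and censored fraction are 568.92 mg/dL and
    56.25 %; at week 6 thirteen of sixteen induced animals saturate the
    meter while three low responders stay below 250 mg/dL (the values the
    study's boxplot rule flags as outliers).  Temperatures are a shared
    N(36.0, 0.25) with no group effect.
    """
    loss_probs = {3: 0.8125, 7: 0.9375}

    ctrl = GroupWeightModel(
        initial_mean=130.57,
        initial_sd=12.29,
        final_mean=349.33,
        final_sd=21.76,
        rho=0.6,
        fractions=(0.0, 0.21, 0.39, 0.54, 0.67, 0.79, 1.0),
        offsets=(0.0,) * 7,
        jitter=(0.0, 3.0, 3.0, 3.0, 3.0, 3.0, 0.0),
    )

    ind_fractions = (0.0, 0.15, 0.35, 0.48, 0.64, 0.82, 1.0)
    ind_jitter = (0.0, 4.0, 4.0, 4.0, 4.0, 4.0, 0.0)
    mu_d = 256.07 - 133.75
    sd_d = float(np.sqrt(10.92**2 + 51.99**2 - 2 * 0.2 * 10.92 * 51.99))
    db3 = _dip_offset(
        loss_probs[3], ind_fractions[2] - ind_fractions[1], mu_d, sd_d, 4.0, 4.0
    )
    db7 = _dip_offset(
        loss_probs[7], 1.0 - ind_fractions[5], mu_d, sd_d, 4.0, 0.0
    )
    b2 = 6.0  # mild fructose-phase lag before the post-STZ dip
    ind = GroupWeightModel(
        initial_mean=133.75,
        initial_sd=10.92,
        final_mean=256.07,
        final_sd=51.99,
        rho=0.2,
        fractions=ind_fractions,
        offsets=(0.0, b2, b2 + db3, 2.0, 8.0, -db7, 0.0),
        jitter=ind_jitter,
    )

    # fed induced glycaemia, week 4: censored mean 568.92, 56.25 % above
    # the 600 mg/dL ceiling
    mu_fed4, sd_fed4 = _solve_censored_normal(0.5625, 568.92)

    glucose = (
        GlucoseWeekModel(
            week=4,
            fasted_mean={"control": 67.00, "induced": 65.06},
            fasted_sd={"control": 8.97, "induced": 19.06},
            fed_mean={"control": 141.00, "induced": mu_fed4},
            fed_sd={"control": 15.22, "induced": sd_fed4},
        ),
        GlucoseWeekModel(
            week=6,
            fasted_mean={"control": 94.63, "induced": 110.63},
            fasted_sd={"control": 8.35, "induced": 30.25},
            fed_mean={"control": 141.63, "induced": 750.0},
            fed_sd={"control": 9.55, "induced": 50.0},
            low_responder_fed_mean=210.0,
            low_responder_fed_sd=25.0,
        ),
    )

    # welfare event probabilities (induced group; controls stay at zero).
    # Onset weeks follow the observed timeline: dehydration from week 2
    # (6/16 animals), grooming loss and orbital narrowing from week 3,
    # curved posture from week 5, diarrhoea and abdominal signs at the
    # end.  Magnitudes keep the expected per-animal weekly total around
    # one at its worst, so the critical total of 4 remains a rare event.
    welfare: dict[str, dict[int, dict[int, float]]] = {
        "Hydration": {
            2: {1: 6 / 16},
            3: {1: 0.12},
            4: {1: 0.12},
            5: {1: 0.15},
            6: {1: 0.15},
            7: {1: 0.18},
        },
        "Hair": {3: {1: 0.15}, 4: {1: 0.15}, 6: {1: 0.15}, 7: {1: 0.18}},
        "GrimaceEyes": {3: {1: 0.15}, 7: {1: 0.03}},
        "Posture": {5: {1: 0.12}, 6: {1: 0.12}, 7: {1: 0.12}},
        "Stool": {7: {1: 0.10, 2: 0.04}},
        "Abdomen": {6: {1: 0.03}, 7: {1: 0.04, 2: 0.08}},
    }

    return SimulationConfig(
        weight={"control": ctrl, "induced": ind},
        weight_loss_prob=loss_probs,
        food_mean={
            "control": (16.0, 18.0, 19.0, 20.0, 21.0, 21.0, 22.0),
            "induced": (10.0, 11.0, 13.0, 26.0, 27.0, 28.0, 28.0),
        },
        food_sd=1.0,
        water_mean={
            "control": (24.0, 25.0, 25.0, 26.0, 26.0, 27.0, 27.0),
            "induced": (34.0, 38.0, 42.0, 70.0, 80.0, 90.0, 95.0),
        },
        water_sd={"control": 2.0, "induced": 6.0},
        glucose=glucose,
        welfare_probs=welfare,
        fasting_ratio={"control": (0.941, 0.008), "induced": (0.918, 0.012)},
        nal_cm={"control": (23.50, 0.79), "induced": (21.03, 1.39)},
        tc_cm={"control": (15.13, 0.60), "induced": (13.22, 1.22)},
        ap_cm={"control": (15.88, 0.70), "induced": (14.38, 1.08)},
        kidney_rel_weight={
            "control": {"right_kidney": (4.053, 0.165), "left_kidney": (3.861, 0.266)},
            "induced": {"right_kidney": (4.952, 0.676), "left_kidney": (4.802, 0.593)},
        },
    )


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------

def _draw_anchors(
    rng: np.random.Generator, model: GroupWeightModel, n: int
) -> tuple[np.ndarray, np.ndarray]:
    cov = model.rho * model.initial_sd * model.final_sd
    mean = [model.initial_mean, model.final_mean]
    covm = [[model.initial_sd**2, cov], [cov, model.final_sd**2]]
    draw = rng.multivariate_normal(mean, covm, size=n)
    w1 = np.clip(draw[:, 0], 60.0, None)
    w7 = np.clip(draw[:, 1], 80.0, None)
    return w1, w7


def _simulate_weights(
    rng: np.random.Generator, model: GroupWeightModel, ids: Sequence[str]
) -> pd.DataFrame:
    n = len(ids)
    w1, w7 = _draw_anchors(rng, model, n)
    rows = []
    for i, wk in enumerate(WEEKS):
        e = rng.normal(0.0, model.jitter[i], size=n) if model.jitter[i] > 0 else np.zeros(n)
        w = w1 + model.fractions[i] * (w7 - w1) + model.offsets[i] + e
        rows.append(
            pd.DataFrame(
                {"animal_id": list(ids), "week": wk, "grams": np.round(w, 2)}
            )
        )
    out = pd.concat(rows, ignore_index=True)
    out["fasting"] = False
    return out


def simulate_cohort(
    config: SimulationConfig | None = None, seed: int | np.random.SeedSequence = 0
) -> CohortDataset:
    """Generate one complete synthetic cohort.

    Identical (config, seed) pairs produce bit-identical datasets.  All
    generated score sheets are valid against the default rubric; fed
    glucose readings pass through the meter-ceiling censoring rule.
    """
    config = config if config is not None else default_config()
    rng = np.random.default_rng(seed)
    rubric = ws.default_rubric()

    groups = {"control": config.n_control, "induced": config.n_induced}
    roster = []
    for grp, n in groups.items():
        prefix = "C" if grp == "control" else "I"
        for i in range(n):
            cage = f"{prefix}{i // config.animals_per_cage + 1}"
            roster.append((f"{prefix}{i + 1:02d}", grp, f"cage_{cage}"))
    animals = pd.DataFrame(roster, columns=["animal_id", "group", "cage_id"])

    # --- weights -----------------------------------------------------------
    wparts = []
    for grp in groups:
        ids = animals.loc[animals["group"] == grp, "animal_id"].tolist()
        wparts.append(_simulate_weights(rng, config.weight[grp], ids))
    weights = pd.concat(wparts, ignore_index=True)

    # --- cage consumption --------------------------------------------------
    crows = []
    for cage_id, sub in animals.groupby("cage_id", sort=True):
        grp = sub["group"].iloc[0]
        n = len(sub)
        for i, wk in enumerate(WEEKS):
            daily_food = max(rng.normal(config.food_mean[grp][i], config.food_sd), 0.5)
            daily_water = max(
                rng.normal(config.water_mean[grp][i], config.water_sd[grp]), 1.0
            )
            food_start = 4000.0
            food_end = food_start - daily_food * n * 7
            row = {
                "cage_id": cage_id,
                "week": wk,
                "food_weight_start_g": round(food_start, 1),
                "food_weight_end_g": round(food_end, 1),
                "n_animals": n,
                "n_days": 7,
                "water_weight_start_g": np.nan,
                "water_weight_end_g": np.nan,
                "water_total_24h_ml": np.nan,
            }
            if wk < config.water_24h_from_week:
                row["water_weight_start_g"] = 6000.0
                row["water_weight_end_g"] = round(6000.0 - daily_water * n * 7, 1)
            else:
                row["water_total_24h_ml"] = round(daily_water * n, 1)
            crows.append(row)
    consumption = pd.DataFrame(crows)

    # --- glucose -----------------------------------------------------------
    ind_ids = animals.loc[animals["group"] == "induced", "animal_id"].to_numpy()
    low_ids = set(
        rng.choice(ind_ids, size=min(config.n_low_responders, len(ind_ids)), replace=False)
    )
    grows = []
    for gw in config.glucose:
        for state in ("fasted", "fed"):
            for grp in groups:
                ids = animals.loc[animals["group"] == grp, "animal_id"].tolist()
                mean = gw.fasted_mean[grp] if state == "fasted" else gw.fed_mean[grp]
                sd = gw.fasted_sd[grp] if state == "fasted" else gw.fed_sd[grp]
                latent = rng.normal(mean, sd, size=len(ids))
                for aid, lv in zip(ids, latent):
                    if (
                        state == "fed"
                        and grp == "induced"
                        and gw.low_responder_fed_mean is not None
                        and aid in low_ids
                    ):
                        lv = rng.normal(
                            gw.low_responder_fed_mean, gw.low_responder_fed_sd
                        )
                    lv = max(float(lv), 20.0)
                    if lv > pm.GLUCOMETER_CEILING:
                        raw: float | str = pm.ABOVE_RANGE
                    else:
                        raw = round(lv, 0)
                    value, censored = pm.censor_glucose(raw)
                    grows.append(
                        {
                            "animal_id": aid,
                            "week": gw.week,
                            "state": state,
                            "raw": raw if isinstance(raw, str) else f"{raw:.0f}",
                            "value_mg_dl": value,
                            "censored": censored,
                        }
                    )
    glucose = pd.DataFrame(grows)

    # --- temperatures ------------------------------------------------------
    trows = []
    for wk in WEEKS:
        t = rng.normal(config.temperature_mean, config.temperature_sd, size=len(animals))
        trows.append(
            pd.DataFrame(
                {
                    "animal_id": animals["animal_id"],
                    "week": wk,
                    "celsius": np.round(np.clip(t, 34.0, 38.0), 1),
                }
            )
        )
    temperatures = pd.concat(trows, ignore_index=True)

    # --- welfare score sheets ---------------------------------------------
    param_names = rubric.names
    srows = []
    for aid, grp in zip(animals["animal_id"], animals["group"]):
        for wk in WEEKS:
            levels = {}
            for p in param_names:
                level = 0
                if grp == "induced":
                    probs = config.welfare_probs.get(p, {}).get(wk)
                    if probs:
                        u = rng.random()
                        acc = 0.0
                        for lv, q in sorted(probs.items()):
                            acc += q
                            if u < acc:
                                level = lv
                                break
                levels[p] = level
            for obs in config.observer_ids:
                obs_levels = dict(levels)
                if config.observer_disagreement > 0:
                    for p in param_names:
                        if rng.random() < config.observer_disagreement:
                            obs_levels[p] = int(
                                rng.choice(sorted(rubric[p].admissible))
                            )
                for p in param_names:
                    srows.append((aid, wk, obs, p, obs_levels[p]))
    scores = pd.DataFrame(
        srows, columns=["animal_id", "week", "observer_id", "parameter", "level"]
    )

    # --- terminal morphometrics and organs --------------------------------
    final = weights[weights["week"] == WEEKS[-1]].set_index("animal_id")["grams"]
    # mean food per animal over the protocol, from the cage records
    cage_daily = consumption.assign(
        daily=lambda d: (d["food_weight_start_g"] - d["food_weight_end_g"])
        / (d["n_animals"] * d["n_days"])
    )
    per_cage_total = cage_daily.groupby("cage_id")["daily"].sum() * 7
    mrows, orows = [], []
    for aid, grp, cage in zip(
        animals["animal_id"], animals["group"], animals["cage_id"]
    ):
        w7 = float(final[aid])
        m = config.weight[grp]
        zw = (w7 - m.final_mean) / m.final_sd if m.final_sd > 0 else 0.0
        rho = config.morpho_rho
        mix = np.sqrt(1 - rho**2)

        def corr_draw(mean_sd: tuple[float, float]) -> float:
            mean, sd = mean_sd
            return mean + sd * (rho * zw + mix * rng.standard_normal())

        fr_mean, fr_sd = config.fasting_ratio[grp]
        fasting_w = w7 * np.clip(rng.normal(fr_mean, fr_sd), 0.85, 0.99)
        mrows.append(
            {
                "animal_id": aid,
                "final_body_weight_g": round(w7, 2),
                "final_fasting_body_weight_g": round(float(fasting_w), 2),
                "nal_cm": round(max(corr_draw(config.nal_cm[grp]), 10.0), 2),
                "tc_cm": round(max(corr_draw(config.tc_cm[grp]), 8.0), 2),
                "ap_cm": round(max(corr_draw(config.ap_cm[grp]), 8.0), 2),
                "total_food_consumption_g": round(float(per_cage_total[cage]), 1),
                "duration_days": pm.DEFAULT_PROTOCOL_DAYS,
            }
        )
        for organ, (mean, sd) in config.kidney_rel_weight[grp].items():
            rel = max(rng.normal(mean, sd), 1.0)
            orows.append(
                {
                    "animal_id": aid,
                    "organ": organ,
                    "weight_g": round(rel * fasting_w / 1000.0, 3),
                }
            )
    morphometrics = pd.DataFrame(mrows)
    organs = pd.DataFrame(orows)

    return CohortDataset(
        animals=animals,
        weights=weights,
        consumption=consumption,
        glucose=glucose,
        temperatures=temperatures,
        scores=scores,
        morphometrics=morphometrics,
        organs=organs,
        config=config,
        rubric=rubric,
    )


# --------------------------------------------------------------------------
# Calibration recovery
# --------------------------------------------------------------------------

def induced_weight_loss_fraction(dataset: CohortDataset, week: int) -> float:
    """Percent of induced animals lighter at ``week`` than the week
    before, via the weight-loss rule of the monitoring pipeline."""
    ind = dataset.animals.loc[dataset.animals["group"] == "induced", "animal_id"]
    w = dataset.weights[dataset.weights["animal_id"].isin(ind)]
    prev = w[w["week"] == week - 1].set_index("animal_id")["grams"].to_dict()
    now = w[w["week"] == week].set_index("animal_id")["grams"].to_dict()
    return pm.weight_loss_fraction(prev, now)


def expected_calibration(config: SimulationConfig) -> dict[str, float]:
    """Model-implied expectations for the recoverable summaries.

    Derived in closed form from the configuration (no simulation), so the
    parameter-recovery check compares Monte-Carlo estimates against
    analytic truths.
    """
    out: dict[str, float] = {}
    for grp, m in config.weight.items():
        means = m.weekly_means()
        out[f"weight_initial_mean_{grp}"] = float(means[0])
        out[f"weight_final_mean_{grp}"] = float(means[-1])
    for wk in config.weight_loss_prob:
        out[f"induced_weight_loss_frac_week{wk}"] = 100.0 * _loss_probability(
            config.weight["induced"], wk
        )
    out["temperature_mean"] = config.temperature_mean
    for gw in config.glucose:
        for grp in ("control", "induced"):
            out[f"glucose_fasted_mean_week{gw.week}_{grp}"] = gw.fasted_mean[grp]
        mu, sd = gw.fed_mean["induced"], gw.fed_sd["induced"]
        p_hi = float(sps.norm.sf(pm.GLUCOMETER_CEILING, mu, sd))
        if gw.low_responder_fed_mean is not None:
            n_sev = config.n_induced - config.n_low_responders
            p_hi = p_hi * n_sev / config.n_induced
        out[f"glucose_fed_censored_frac_week{gw.week}"] = p_hi
    probs = config.welfare_probs.get("Hydration", {}).get(2, {})
    out["hydration_event_frac_week2"] = float(sum(probs.values()))
    return out


def recover_calibration(datasets: Sequence[CohortDataset]) -> pd.DataFrame:
    """Empirical means of the calibrated summaries over many replicates.

    Returns a table with one row per recoverable quantity: the recovered
    Monte-Carlo mean, its standard error across replicates, and the
    configured (analytic) expectation.  Requires >= 100 replicates.
    """
    if len(datasets) < 100:
        raise ValueError("at least 100 replicates are required")
    config = datasets[0].config
    if config is None:
        raise ValueError("datasets carry no generating configuration")
    expected = expected_calibration(config)

    per_rep: dict[str, list[float]] = {k: [] for k in expected}
    for ds in datasets:
        merged = ds.weights.merge(ds.animals[["animal_id", "group"]], on="animal_id")
        for grp in ("control", "induced"):
            sub = merged[merged["group"] == grp]
            per_rep[f"weight_initial_mean_{grp}"].append(
                sub.loc[sub["week"] == 1, "grams"].mean()
            )
            per_rep[f"weight_final_mean_{grp}"].append(
                sub.loc[sub["week"] == WEEKS[-1], "grams"].mean()
            )
        for wk in config.weight_loss_prob:
            per_rep[f"induced_weight_loss_frac_week{wk}"].append(
                induced_weight_loss_fraction(ds, wk)
            )
        per_rep["temperature_mean"].append(ds.temperatures["celsius"].mean())
        g = ds.glucose.merge(ds.animals[["animal_id", "group"]], on="animal_id")
        for gw in config.glucose:
            for grp in ("control", "induced"):
                sel = (
                    (g["week"] == gw.week)
                    & (g["state"] == "fasted")
                    & (g["group"] == grp)
                )
                per_rep[f"glucose_fasted_mean_week{gw.week}_{grp}"].append(
                    g.loc[sel, "value_mg_dl"].mean()
                )
            sel = (g["week"] == gw.week) & (g["state"] == "fed") & (
                g["group"] == "induced"
            )
            per_rep[f"glucose_fed_censored_frac_week{gw.week}"].append(
                g.loc[sel, "censored"].mean()
            )
        ind_ids = ds.animals.loc[ds.animals["group"] == "induced", "animal_id"]
        s = ds.scores
        sel = (
            s["animal_id"].isin(ind_ids)
            & (s["week"] == 2)
            & (s["parameter"] == "Hydration")
            & (s["observer_id"] == config.observer_ids[0])
        )
        per_rep["hydration_event_frac_week2"].append((s.loc[sel, "level"] > 0).mean())

    rows = []
    r = len(datasets)
    for key, vals in per_rep.items():
        arr = np.asarray(vals, dtype=float)
        rows.append(
            {
                "quantity": key,
                "recovered": arr.mean(),
                "se": arr.std(ddof=1) / np.sqrt(r),
                "configured": expected[key],
                "n_replicates": r,
            }
        )
    return pd.DataFrame(rows)
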