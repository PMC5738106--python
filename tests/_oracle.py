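"""Brute-force fixed-step integrator used as an independent oracle.

Replays an event timeline with classical RK4 at a fixed 0.01-min step
instead of the package's closed-form exponential stepping.  Kept free of any
midasim integration code on purpose: it shares only the event semantics
(well-mixed transfers, proportional sampling, oral hold, glucogenic pool
reacting intestinally) so that agreement between the two is informative.
"""

from __future__ import annotations


def simulate_fixed_step(food, timeline, kinetics, dt_min: float = 0.01):
    """Return {(time, purpose): (starch_g, glucose_g)} for every sample event."""
    comps = {
        name: {"volume": 0.0, "starch": 0.0, "glucose": 0.0, "glucogenic": 0.0}
        for name in ("oral", "gastric", "intestinal")
    }
    g_rate = (kinetics.glucogenic_rate if kinetics.glucogenic_rate is not None
              else kinetics.k_intestinal)
    rates = {"oral": kinetics.k_oral, "gastric": kinetics.k_gastric,
             "intestinal": kinetics.k_intestinal}
    y = kinetics.glucose_yield
    oral_active = True

    def derivs(name, s, p):
        k = rates[name] if (name != "oral" or oral_active) else 0.0
        gp = g_rate if name == "intestinal" else 0.0
        ds = -k * s
        dp = -gp * p
        dg = y * (k * s + gp * p)
        return ds, dg, dp

    def rk4_advance(n_steps: int) -> None:
        for _ in range(n_steps):
            for name, c in comps.items():
                s, g, p = c["starch"], c["glucose"], c["glucogenic"]
                k1 = derivs(name, s, p)
                k2 = derivs(name, s + 0.5 * dt_min * k1[0], p + 0.5 * dt_min * k1[2])
                k3 = derivs(name, s + 0.5 * dt_min * k2[0], p + 0.5 * dt_min * k2[2])
                k4 = derivs(name, s + dt_min * k3[0], p + dt_min * k3[2])
                c["starch"] = s + dt_min / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
                c["glucose"] = g + dt_min / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
                c["glucogenic"] = p + dt_min / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])

    records = {}
    step_now = 0
    for ev in timeline.events:
        ev_step = round(ev.time_min / dt_min)
        rk4_advance(ev_step - step_now)
        step_now = ev_step
        c = comps.get(ev.compartment)
        if ev.kind == "phase_change":
            if ev.compartment == "oral":
                oral_active = False
        elif ev.kind == "add_food":
            c["volume"] += ev.volume_ml
            c["starch"] += food.starch_conc * ev.volume_ml
            c["glucose"] += food.glucose_conc * ev.volume_ml
            c["glucogenic"] += food.glucogenic_conc * ev.volume_ml
        elif ev.kind == "add_fluid":
            c["volume"] += ev.volume_ml
        elif ev.kind in ("feed_pulse", "pyloric_pulse"):
            src = comps["oral"] if ev.kind == "feed_pulse" else comps["gastric"]
            v = min(ev.volume_ml, src["volume"])
            if src["volume"] > 0:
                frac = v / src["volume"]
                for key in ("starch", "glucose", "glucogenic"):
                    moved = src[key] * frac
                    src[key] -= moved
                    c[key] += moved
                src["volume"] -= v
                c["volume"] += v
        elif ev.kind == "sample":
            if ev.compartment == "food":
                records[(ev.time_min, ev.purpose)] = (
                    food.starch_conc * ev.volume_ml, food.glucose_conc * ev.volume_ml)
                continue
            frac = ev.volume_ml / c["volume"]
            records[(ev.time_min, ev.purpose)] = (c["starch"] * frac, c["glucose"] * frac)
            for key in ("starch", "glucose", "glucogenic"):
                c[key] -= c[key] * frac
            c["volume"] -= ev.volume_ml
    return records
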