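# retortsim

Thermal-sterilization simulation of canned purees: axisymmetric natural
convection in a sealed tin, dynamic F-value (lethality) fields, cold-point
detection, and retort-schedule optimization against overheating.

## The problem

Viscous puree products (chestnut, taro, …) brown near the can wall during
retorting: the wall region spends far longer at sterilizing temperature than
the slowest-heating zone (SHZ) that actually limits safety.  Process design
must guarantee commercial sterility at the SHZ — a target F₀ at the cold
point — while keeping the *overheated zone* (OZ), the volume whose F exceeds
a quality threshold, as small as possible.  `retortsim` lets a process
engineer simulate a retort program, find the cold point, score both criteria,
and search for gentler (e.g. two-stage) schedules.

## The model

Conjugate heat transfer in the (r, z) half-plane of a cylindrical can whose
inner surface follows the retort temperature:

* energy:  ρCp ∂T/∂t + ρCp **u**·∇T = ∇·(k∇T)
* momentum (creeping flow):  ρ₀ ∂**u**/∂t = −∇P + ∇·(μ∇**u**) + (ρ₀ − ρ(T))g **ẑ**
* continuity:  ∇·**u** = 0 (enforced exactly by a coupled velocity–pressure solve)

with temperature-dependent ρ, μ, k of the default chestnut puree and a
stagnant conductive vapor headspace.  Lethality follows the general method:

* F(r, z) = ∫ 10^((T(°C) − 121.1)/10) dt   [minutes; Z = 10 °C]

The cold point is the minimum-F puree cell; OZ is the puree-volume fraction
with F > 25 min.  Retort programs use canning shorthand: `"10-86-24/121"` is
a 10 min come-up to 121 °C, an 86 min hold, and a 24 min cool.
See `docs/methods.md` for assumptions, numerics and limitations.

## Worked example

Simulate the original single-stage process in conduction mode on a coarse
grid (seconds of runtime):

```sh
retortsim run --schedule "10-86-24/121" --mode conduction \
    --grid 12x24 --dt 5 --probe 0.0,0.0188 --out results/demo
```

prints (and writes to `results/demo/summary.json`):

```json
{
  "schedule": "10-86-24/121",
  "mode": "conduction",
  "grid": "12x24",
  "F_min": 3.6867777453970207,
  "F_max": 81.14200187432483,
  "cold_point_r_m": 0.0020604166666666666,
  "cold_point_z_m": 0.1134375,
  "oz_fraction": 0.4076086956521739,
  "threshold_min": 25.0,
  "RT_C": 121.1,
  "Z_C": 10.0
}
```

Reading: after the full 120-minute cycle the slowest cell accumulated only
F = 3.7 min while the wall region reached F = 81 min — a 22× spread — and
41 % of the puree exceeded the F > 25 browning threshold.  Without buoyant
flow the cold spot sits high in the can (z = 0.113 m, capped by the
insulating headspace); in `--mode convection` the circulation drags it to
the near-bottom axis (z ≈ 0.019 m).  The run also writes the probe series
CSV (`t_s, T_K, lethal_rate, F_min_accumulated`) and the final
temperature/F fields as legacy VTK and long-format CSV.

Compare the enterprise schedule against the gentler two-stage program:

```sh
retortsim compare --baseline "10-86-24/121" \
    --candidate "10-65-48-14/118-110" --target-f 4.5
```

and `retortsim validate --pred pred.csv --meas meas.csv` scores a predicted
probe curve against a measured one (RMSE, maximum deviation, and the
general-method F of both).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the headline quantities of the reference process
study on the default can (convection mode, 24×48 grid, dt = 1 s): the
cold-point height of the original `10-86-24/121` process, the F > 25
volume percentages of the original and adjusted `10-65-48-14/118-110`
processes, and the general-method F integrated over the simulated
cold-point probe series of the adjusted process.  The pipeline is
deterministic; `--seed` only feeds the probe-noise generator, which does
not enter the reported values.  Expect ~10 minutes on one CPU.
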