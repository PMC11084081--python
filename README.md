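# equilimb

Static musculoskeletal analysis of the standing equine hindlimb, built for
implant-design workflows (e.g. femoral osteosynthesis) that need realistic
muscle and joint loads as boundary conditions for finite-element analysis.

In square standing, each hindlimb carries about 20% of body weight at the
hoof. Gravity and this ground reaction force produce net moments about the
coxofemoral (hip), femorotibial (stifle) and femoropatellar joints that the
muscles and patellar ligaments must cancel. Because far more actuators
cross these joints than there are balance equations, the force
distribution is resolved by static optimization: minimize the cubic
muscle-stress cost

```
min U = Σ_i (F_i / PCSA_i)³       subject to   A · F = M,   F_lo ≤ F ≤ F_hi
```

where `PCSA_i` is the physiological cross-sectional area, `A` stacks the
per-joint moment coefficients `τ × r̂` (lever arm from joint center to
attachment, crossed with the unit line of action), and `M` collects the
moments needed to oppose the external loading. Bounds encode physiology:
each muscle's floor is 1% of its maximum isometric force (resting tonus),
its cap is the maximum isometric force, the superficial digital flexor
carries at least 90% of the GRF (standing in for the hock-stabilizing
mechanism outside the three-joint model), and ligaments have a floor of
zero. Joint contact forces follow as `F_contact = Σ F_segmental +
Σ F_muscles`, and the femoral FEA load case collects every femur-attached
muscle force exceeding 100 N, uniformly distributed over labeled
attachment areas, with the femoral condyles treated as bearings (medial
fixed, lateral constrained proximo-distally and antero-posteriorly).

The package provides:

- `equilimb.geometry` — data model, femoral-head sphere fit, epicondyle
  midpoint and contact-point joint centers, YAML geometry I/O;
- `equilimb.statics` — GRF, segment gravity loads, net joint moments;
- `equilimb.system` — assembly of the moment-balance matrix;
- `equilimb.optimize` — the cubic static optimization with bound rules,
  a KKT optimality certificate, and a brute-force test oracle;
- `equilimb.contact`, `equilimb.report`, `equilimb.loadcase` — contact
  forces, muscle-group sums and implant safety factors, FEA export;
- `equilimb.synthetic` — seeded generator of feasible synthetic limbs;
- `StandingLimbModel` / `StandingLimbResults` — the high-level interface;
- an `equilimb` CLI with `solve`, `report` and `simulate` subcommands.

## Worked example

```python
from equilimb import StandingLimbModel, synthetic

inst = synthetic.generate(seed=7, n_actuators=12)   # feasible by construction
res = StandingLimbModel.from_instance(inst).fit()
print(res.summary())
```

```
Standing hindlimb static optimization
=====================================================
actuators: 12   joints: 3
converged: True   method: slsqp+newton   iterations: 84
objective U = sum (F/PCSA)^3: 3.552878e+16
moment residual |A F - M|: 4.392e-13 N·m
KKT (projected gradient, relative): 1.798e-15
-----------------------------------------------------
actuator                         force (N)     bound
actuator_00                         1501.8
actuator_01                          136.3
actuator_02                         1227.2
...
actuator_09                            3.3     lower
```

The moment residual says the optimized forces balance the target joint
moments to numerical precision; the KKT value certifies global optimality
(the cubic cost is convex for non-negative forces); `lower` flags muscles
resting at their 1%-tonus floor. `res.contact_forces()` returns per-joint
contact vectors and magnitudes, and `res.load_case()` the femoral FEA
entries (here 4 of the 12 actuators attach to the femur with more than
100 N).

Derived reports work from any force table. With the shipped standing-limb
solution table, the four quadriceps heads sum to 951 N, and the Ti6Al4V
yield strengths (−1074 / 982 MPa) over the worst-case screw peak stresses
(−348 / 197 MPa) give safety factors 3.1 and 5.0:

```sh
equilimb report forces.csv --group "quadriceps=m. vastus medialis;m. vastus lateralis;m. rectus femoris;m. vastus intermedius"
```

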