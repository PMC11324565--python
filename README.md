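# pcbdechlor

Congener-level analytics for **microbial reductive dechlorination of
polychlorinated biphenyls (PCBs)**.

Anaerobic consortia (typically harbouring *Dehalococcoides* and related
organohalide-respiring bacteria) strip chlorines one at a time from PCB
mixtures such as Aroclor 1260, preferentially from the *meta* and
*para* ring positions. Environmental-microbiology studies quantify this
from GC–MS congener tables and 16S amplicon data; this package
implements that analysis chain as a tested, reusable library for
anyone working with congener time courses:

* **Congener space** — enumeration and canonicalization of all 209
  chlorobiphenyls under biphenyl symmetry, Ballschmiter–Zell numbering
  (with the historically irregular 107–109/199–201 assignments pinned
  to the literature), ortho/meta/para accounting, molecular weights,
  structure-string parsing (`2,2',4,4'` or `24-24`).
* **Dechlorination metrics** — average chlorines per biphenyl
  N̄(t) = Σ_c x_c·n_Cl(c) from mole-percent profiles, chloride-release
  rates r = ΔN̄ · C_molar / Δt (μM Cl⁻ d⁻¹), rate fold changes, and
  per-position removal fractions 1 − N_p(t)/N_p(0).
* **Pathway inference** — the directed acyclic network of
  single-chlorine removals over the 209-congener space, position- and
  flanking-annotated, with BFS reachability (e.g. PCB153 → PCB47 by
  meta removals only) and rule-based classification of steps into the
  named dechlorination processes N and H/H′ (configurable
  chlorophenyl-group → position tables).
* **Synthetic data** — a first-order kinetic simulator on the reaction
  network (matrix-exponential solution, exact per-reaction chloride
  ledger, lag phase, measurement noise, detection limit) that emulates
  Aroclor 1260-like time courses, and a Gaussian-copula abundance
  generator that plants Spearman-correlated taxon blocks in
  compositional genus tables.
* **Co-occurrence networks** — the standard microbiome workflow:
  abundance filter (> 0.01%), pairwise Spearman with exact permutation
  p-values for small n, |r| > 0.7 and p < 0.05 thresholds, and the
  usual topology metrics (degree, density, clustering, modularity,
  path lengths, components).

## Worked example

Simulate a humin-amended ("HM-like") culture against a slower control
from the same pseudo-Aroclor 1260 starting mixture, then compute the
headline metrics:

```python
from pcbdechlor import (pseudo_aroclor, SimulationSpec, simulate, build_network,
                        average_chlorine, dechlorination_rate,
                        positional_removal, fold_change)

start = pseudo_aroclor(6.34, seed=1)          # avg 6.34 Cl per biphenyl
net = build_network()                          # all 840 single-removal edges

hm = SimulationSpec(system="HM-like", initial_profile=start, target_avg_cl=None,
                    lag_days=10.0, times=(0.0, 15.0, 112.0),
                    base_rates={"ortho": 0.0, "meta": 0.03, "para": 0.005}, seed=1)
bla = SimulationSpec(system="control-like", initial_profile=start, target_avg_cl=None,
                     lag_days=21.0, times=(0.0, 15.0, 112.0),
                     base_rates={"ortho": 0.0, "meta": 0.015, "para": 0.004}, seed=1)

res_hm, res_bla = simulate(hm, net), simulate(bla, net)
r_hm = dechlorination_rate(res_hm.clean_timecourse, 0.0, 112.0)
r_bla = dechlorination_rate(res_bla.clean_timecourse, 0.0, 112.0)
print(round(r_hm.rate_um_cl_per_d, 2),                     # 1.8  uM Cl-/d
      round(r_bla.rate_um_cl_per_d, 2),                    # 1.4  uM Cl-/d
      round(fold_change(r_hm.rate_um_cl_per_d,
                        r_bla.rate_um_cl_per_d), 2))       # 1.29

pr = positional_removal(res_hm.clean_timecourse, 0.0, 112.0)
print(round(pr.removal_fraction["meta"], 3),               # 0.953
      round(pr.removal_fraction["para"], 3))               # 0.4

# the simulator's chloride ledger reproduces the metric exactly
print(round(res_hm.chloride_released(112.0), 4),           # 3.0112 Cl/biphenyl
      round(r_hm.delta_avg_cl, 4))                         # 3.0112

ok, path = build_network(allowed={"meta"}).reachable(153, [47])
print(" -> ".join(f"PCB{c.bz}" for c in path))             # PCB153 -> PCB99 -> PCB47
```

Reading: the amended culture releases chloride at 1.8 μM Cl⁻ d⁻¹ over
112 days, 1.29× the control; 95% of its meta chlorines but only 40% of
its para chlorines are removed (meta-biased kinetics); and the dominant
end product PCB47 is two meta removals downstream of PCB153. The
chloride ledger — an independent per-reaction account kept by the
simulator — agrees with the profile-derived ΔN̄ to machine precision.

The same stages are available from the shell:

```bash
pcbdechlor enumerate --out congeners.csv
pcbdechlor simulate --config sim.yaml --seed 7 --out tc.csv
pcbdechlor metrics tc.csv --window 0:15 --window 0:112 --out metrics.csv
pcbdechlor pathways --positions meta --parent 153 --target 47
pcbdechlor simulate-abundances --config abund.yaml --seed 7 --out abund.csv
pcbdechlor network abund.csv --metrics-out topology.json
pcbdechlor run --config pipeline.yaml --out-dir results/
```

`run` chains stages from one YAML file and writes a `report.json`
embedding the seed, package version and config hash; identical
config + seed reproduces the report byte for byte.

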