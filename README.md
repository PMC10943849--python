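# pcbdechlor

Analytics for microbial reductive dechlorination of polychlorinated
biphenyls (PCBs) in anaerobic microcosms, for environmental microbiologists
and biogeochemists who assay dechlorination activity in sludge or sediment
incubations and profile the associated microbial communities.

The package covers the full computational chain of such a study:

1. **Congener structural model** — the 209 PCB congeners in
   chlorophenyl-ring notation (e.g. `2345-245`), canonicalized under the
   order-8 molecular symmetry group, with ortho/meta/para position classes,
   flanking context of each chlorine, and all single-dechlorination
   parent → daughter relations.
2. **Dechlorination statistics** — the average chlorines per biphenyl,
   Cl/PCB = Σᵢ xᵢ·nᵢ (xᵢ mole fraction, nᵢ chlorine count of congener *i*);
   its decrease ΔCl/PCB from day 0 (total and per position class);
   activity calling against an abiotic-control threshold (0.05); lag-time
   intervals; para/meta preference classification by one-way ANOVA across
   replicates; pathway graphs over observed congeners with non-negative
   least-squares flux attribution.
3. **qPCR quantification** — log-linear standard curves
   (Cq = b + m·log₁₀ copies, efficiency E = 10^(−1/m) − 1), inversion with
   limit-of-detection flags, summed RDase-gene/OHRB-cell ratios with a
   10-fold uncertainty band, and > 90 % single-genus dominance calls for
   *Dehalococcoides*, *Dehalogenimonas* and *Dehalobacter*.
4. **Community ecology** — OHRB screening (including uncultivated
   Dehalococcoidia lineages S085, vadinBA26, GIF9, DscP2, t0.6.f), alpha
   diversity, Bray–Curtis/PCoA, prevalence-filtered Spearman co-occurrence
   networks (|ρ| > 0.6, Benjamini–Hochberg-adjusted p < 0.01), and the
   normalized stochasticity ratio (NST) with a multinomial regional-pool
   null model (1000 randomizations, 50 % boundary).
5. **Synthetic data** — seeded forward models of all of the above
   (first-order positional dechlorination kinetics, qPCR dilution series,
   community count tables with stochastic or deterministic assembly), so
   every stage is testable without laboratory data.

## Worked example

Simulate a microcosm spiked with a hexa/hepta-dominated congener mixture
and summarize its dechlorination:

```python
from pcbdechlor import (KineticConfig, simulate_microcosm, cl_per_pcb,
                        delta_cl, call_activity, lag_time)

cfg = KineticConfig(seed=7, replicates=3)      # 30-day lag, 5 % noise
sim = simulate_microcosm(cfg)
obs = sim.observed[0]
print({d: round(cl_per_pcb(obs.profile_at(d)), 3) for d in obs.days})
d = delta_cl(obs, 180.0)
print("dCl/PCB(180) = %.3f  (ortho %.3f, meta %.3f, para %.3f)"
      % (d["total"], d["ortho"], d["meta"], d["para"]))
print("active:", call_activity(obs), " lag interval:", lag_time(obs))
```

prints

```
{0.0: 6.362, 30.0: 6.369, 60.0: 6.276, 90.0: 6.194, 120.0: 6.117, 150.0: 6.05, 180.0: 5.992}
dCl/PCB(180) = 0.370  (ortho 0.023, meta 0.221, para 0.125)
active: True  lag interval: LagInterval(prev_day=30.0, onset_day=60.0)
```

The mixture starts at ~6.4 chlorines per biphenyl; after the 30-day lag
the microcosm removes 0.37 chlorines per biphenyl in 180 days — mostly
flanked meta and para chlorines, with minor ortho removal — and is called
active (ΔCl/PCB ≥ 0.05), with onset between the day-30 and day-60
samplings.

A complete miniature study (microcosms + replicates + abiotic control +
qPCR panel + community tables) can be generated and analyzed end to end
from the shell:

```bash
pcbdechlor simulate --out study --seed 1
pcbdechlor --verbose report --config study/config.yaml
```

which writes per-stage CSV/TSV/GraphML/JSON outputs and a run manifest
(versions, seed, thresholds, input checksums, filter counts) under
`study/results/`.

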