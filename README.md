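# lipoarm

Trajectory analysis of the induced release of the aminomethyl lipoate arm
from glycine-cleavage protein H.

## The problem

In the glycine cleavage system (GCS), shuttle protein H carries a lipoate
"swinging arm". In the intermediate form (H_int) the arm bears an
aminomethyl moiety (–CH₂–NH₂⁺) that is vulnerable to hydroxide attack, so it
is protected inside a cavity of protein H — pinned by *charged hydrogen
bonds* between the arm's positively charged nitrogens (N17, N6) and polar
cavity residues — until protein T docks and induces its release. The release
proceeds through five conformational states, each defined by the dominant
hydrogen-bond partner of the arm:

| State | hallmark bond | role |
|-------|---------------|------|
| I     | N17 ↔ Glu-12 / Glu-14 | protected state |
| II    | N17 ↔ Ser-67          | rate-limiting trap (β7 sheet) |
| III   | N17 ↔ Asp-68          | arm starts to leave |
| IV    | N17 ↔ Tyr-70          | cavity edge |
| V     | N6  ↔ Leu-35          | arm has completely left |

`lipoarm` implements the analyses that quantify this process:

* **Geometric H-bond detection** over flagged donor/hydrogen/acceptor
  triples (defaults r(D–A) ≤ 3.5 Å, ∠(H–D–A) ≤ 30°), with charged-bond
  classification and per-pair occupancies.
* **State segmentation**: per-frame State I–V labels from hallmark bonds,
  majority-vote smoothing, a furthest-state-reached convention, and a step
  report (dwell times of steps 1–4 and the release time).
* **Reaction coordinate** d = |N17 − COM(Glu-12, Glu-14)| and per-frame
  RMSD series (Kabsch superposition, first frame as reference).
* **WHAM**: the potential of mean force F(d) = −k_BT ln P(d) from
  umbrella-sampling windows, via self-consistent iteration of
  P(x) = Σᵢ nᵢ(x) / Σⱼ Nⱼ fⱼ e^(−β wⱼ(x)),  fⱼ⁻¹ = Σₓ P(x) e^(−β wⱼ(x)),
  with window-overlap diagnostics and valley/peak barrier extraction.
* **Clustering**: neighbor-count (GROMOS-style) clustering on a pairwise
  RMSD matrix and centroid-most representative-frame selection.
* **Reporting**: per-variant release-time table and its Pearson correlation
  with user-supplied enzyme activities.

Because the underlying all-atom MD trajectories are not redistributable, a
first-class `lipoarm.synthetic` subpackage generates every input the
pipeline needs: toy structural trajectories that realize the hallmark bond
geometry of a planted state schedule (wild type plus the Ser-67 mutants
S67Q, S67Y, S67V, S67P), and overdamped Langevin umbrella samples on a
reference free-energy landscape whose main barrier (peak F minus valley C)
is 14.6 kJ/mol.

## Worked example

```python
import numpy as np
from lipoarm import contact_table, label_frames, smooth_labels, step_report
from lipoarm import reaction_coordinate, wham, barrier
from lipoarm.topology import AtomSelection
from lipoarm.synthetic import (variant_schedule, generate_release_trajectory,
                               build_reference_landscape,
                               generate_umbrella_windows)

traj = generate_release_trajectory(variant_schedule("WT"), seed=7)
table = contact_table(traj,
                      arm_selection=AtomSelection(chain_id="L"),
                      cavity_selection=AtomSelection(chain_id="A"))
rep = step_report(smooth_labels(label_frames(table)))
print({k: round(v, 1) for k, v in rep.step_durations_ns.items()},
      rep.release_time_ns)

d = reaction_coordinate(traj)          # Å, per frame
print(round(float(np.median(d.values[d.times < 40.0])), 2))

landscape = build_reference_landscape()
profile = wham(generate_umbrella_windows(landscape, seed=7))
print(round(barrier(profile, (7, 9), (14.5, 16.5)).height, 2))
```

prints

```
{'step1': 40.0, 'step2': 199.9, 'step3': 20.1, 'step4': 20.0} 280.0
2.77
14.05
```

i.e. the wild-type arm dwells 40 ns in the protected state, ~200 ns trapped
by Ser-67, ~20 ns each at Asp-68 and Tyr-70, and is released at 280 ns
(boundaries recovered to within a frame of the planted schedule); the
protected-state N17–COM distance sits near 2.8 Å (inside the 2.5–3.0 Å
band); and WHAM recovers the 14.6 kJ/mol main barrier from the biased
window samples to within the seed-to-seed spread (~±0.6 kJ/mol).

The same pipeline is available from the shell:

```bash
lipoarm --seed 7 --out run pipeline     # all variants + WHAM + correlation
lipoarm --seed 7 --out run simulate-traj --variant S67V
lipoarm --seed 7 --out run states run/S67V.pdb
```

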