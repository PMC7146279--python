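# hingescope

Hinge-bending domain-motion analysis for two-domain enzymes.

Many peptidases — angiotensin I converting enzyme (ACE) and its
homologue ACE2 among them — work like a Pac-Man: two subdomains flank a
deep active-site cleft and open and close about a hinge to admit
substrate and release product. `hingescope` quantifies that motion from
structures and trajectories in PDB format, for structural biologists
and simulation analysts who want the standard mouth-opening observables
without gluing together ad-hoc scripts:

* **Lip-center distance** — the distance between the geometric centers
  of the Cα atoms of two "lips" (residue sets on either subdomain
  flanking the cleft): `d = |⟨x⟩_lipI − ⟨x⟩_lipII|`.
* **Conformational state** — closed (`d < 15 Å`), open (`d > 20 Å`) or
  semi-open (between, boundaries inclusive to semi-open), plus state
  occupancies and the number of closed↔open conversions along a
  trajectory.
* **Hinge-bending angle** — the magnitude of the rigid rotation of
  subdomain I relative to subdomain II, from a two-stage Kabsch
  superposition anchored on subdomain II:
  `θ = arccos((tr R − 1)/2)`.
* **RMSD / RMSF** — Cα RMSD against the initial structure and
  per-residue RMSF about the two-pass mean structure.
* **Hydrogen-bond counting** — geometric detection with the
  donor–acceptor distance ≤ 3.3 Å and H–D–A angle ≤ 30° criteria,
  reported per frame as mean ± sd.
* **Synthetic hinge trajectories** — a two-rigid-domain toy enzyme with
  a programmable hinge-angle schedule, Gaussian coordinate noise and
  exact ground truth, so every stage above can be validated without
  running molecular dynamics.

Region presets are included for the somatic-ACE C domain (entry 4APH
numbering) and ACE2 (1R4L/1R42 numbering).

## Worked example

Generate a 400-frame synthetic trajectory whose mouth opens and closes
sinusoidally, then analyze it:

```sh
hingescope simulate --schedule sin --amplitude 25 --period 40 \
    --frames 80 --noise 0.1 --seed 42 --out toy/
# wrote 80 frames (200 atoms) to toy; theta_open = 19.66 deg

hingescope analyze --topology toy/trajectory.pdb --regions toy/regions.yaml \
    --timestep 0.2 --equilibration 2.0 --out results/
```

which prints (abridged):

```json
{
  "hinge": {
    "occupancy": {"closed": 0.406, "semi_open": 0.217, "open": 0.377},
    "n_conversions": 3,
    "distance_A": {"min": 8.99, "max": 22.93, "mean": 16.69}
  },
  "rmsd_A": {"max": 6.98, "mean": 3.55}
}
```

`theta_open = 19.66°` is the hinge rotation at which the toy's mouth
crosses the 20 Å open threshold. The occupancies say the trajectory
spends ~41 % of production frames closed and ~38 % open, and
`n_conversions: 3` counts how often it went all the way between the
closed and open states (semi-open excursions do not count). Per-frame
tables (`hinge_timeseries.csv`, `rmsd_timeseries.csv`,
`rmsf_profile.csv`) and a provenance echo land in `results/`.

The same machinery works on real structures. With PDB entries on disk:

```sh
hingescope compare --closed 1R4L.pdb --open 1R42.pdb --regions ace2
```

prints both lip distances and the interdomain hinge angle between the
closed (inhibitor-bound) and open (free) ACE2 crystal forms.

As a library:

```python
from hingescope import (SyntheticHingeParams, SinusoidalSchedule,
                        generate_hinge_trajectory, analyze_trajectory)

params = SyntheticHingeParams(angle_schedule=SinusoidalSchedule(25, 400),
                              noise_sd=0.1, n_frames=2000, seed=7)
traj, truth, toy = generate_hinge_trajectory(params)
result = analyze_trajectory(traj, toy.regions, reference=toy.frame)
print(result.occupancy, result.n_conversions)
```

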