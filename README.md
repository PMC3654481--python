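# ermdquant

Spatial statistics for **ER-associated mitochondrial division (ERMD)**:
where do mitochondria divide relative to ER–mitochondria contact-site foci,
how much mitochondrial surface is in contact with the ER, and how fast do
constrictions resolve into independent tips?

The package is aimed at cell biologists quantifying organelle contact sites
and division dynamics in budding yeast (or similar tubular-network systems)
from fluorescence time-lapse data and electron-tomogram surface models. It
provides:

* **`ermdquant.association`** — the division–focus association statistic:
  an event is linked to a focus when the focus center lies within
  r_link = 300 nm (1.5× the 205 nm mean focus radius); the observed linked
  fraction p̂ = n_linked/n is compared against a random-placement null

  p_null = ρ · (r_link / r_focus)², with ρ the measured focus/mitochondria
  area ratio (per-plane mean). With ρ = 4.5%: 0.045 × (300/205)² = 9.6 %
  ≈ 10 % random chance. A Monte-Carlo null on the actual surface and a
  one-sided exact binomial enrichment test P(X ≥ n_linked | n, p_null)
  complete the inference.
* **`ermdquant.contacts`** — tomogram-style contact quantification on
  triangle meshes: mitochondrial faces within 30 nm of the ER with no
  ribosome between the membranes, segmented into connected patches;
  per-patch areas, percent-of-surface in contact, inter-contact distances,
  short-axis diameter profiles and constriction metrics.
* **`ermdquant.kinetics`** — censored resolution-time analysis of tip
  tracks: time from constriction onset until the inter-tip distance exceeds
  500 nm for ≥2 consecutive frames; tracks persisting through the 210 s
  capture are right-censored ("never"); frequency profiles and an exact
  resolved-vs-never group test.
* **`ermdquant.synthetic`** — a scene generator producing tubular networks,
  surface foci (4.5% coverage), division events with controllable
  association probability, ER wraps with closed-form ground-truth contact
  areas, ribosomes, nucleoids and tip tracks — so every estimator is tested
  against known truth without any external data.

Everything is importable as a library, drivable from the `ermdquant` CLI
(`simulate | associate | contacts | kinetics | run`), and exercised by the
numbered narratives under `analysis/`.

## Worked example

```sh
python analysis/01_simulate_scene.py --seed 1   # writes results/scene/
python analysis/02_division_focus_association.py --seed 1
```

prints

```
division-focus association
  observed linked fraction: 0.667 (generator truth 0.667)
  per-plane area ratio:     0.0437
  analytic null:            0.0936
  Monte-Carlo null:         0.1403 +/- 0.0019
  enrichment p-value:       4.32e-27
  nucleoid-division linked fraction: 0.967 (truth 0.867)
```

Reading this: 66.7% of the 60 simulated division events sit within 300 nm
of a focus — exactly the generator's drawn association labels. The
thresholded stacks give a 4.4% focus/mitochondria area ratio, so a randomly
placed division would be linked only ~9.4% of the time under the flat-disk
dilation null (the Monte-Carlo null on the curved tube surface is a bit
higher, ~14%, because a 300 nm ball wraps around a 200 nm-radius tube);
either way the observed fraction is enriched at p ≈ 10⁻²⁷.

```sh
python analysis/04_resolution_kinetics.py --seed 1
```

```
resolution-time frequency profiles (n=29 per group)
  wild-type-like  [0,15] s: 1, (15,60] s: 26, (60,210] s: 2, never: 0
  mutant-like     [0,15] s: 0, (15,60] s: 0, (60,210] s: 0, never: 29
  resolved-fraction difference: 1.00 (95% CI 0.83..1.00), exact p = 6.65e-17
```

A wild-type-like cohort resolves almost entirely within 15–60 s, while the
mutant-like cohort never resolves within the 210 s capture; the exact test
on resolved-vs-never counts separates the groups decisively.

`analysis/03_contact_quantification.py` runs the paired contact scenes
(wild-type-like: two large ER wraps; mutant-like: eight smaller wraps on
the same mitochondrial surface) and recovers the generator-set ~3× total
contact-area difference along with the patch-count and patch-size
orderings.

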