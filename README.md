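# evospectra

Evolutionary assembly of generalised Lotka–Volterra (GLV) food webs and
the geometry of their community-matrix eigenvalue spectra.

Random matrix theory predicts elliptical eigenvalue spectra for
community matrices and, with it, instability of large food webs. Webs
that *self-assemble* through an evolutionary process look different:
their spectra become bi-modal along the real axis — a large peak of
eigenvalues with small negative real parts and a secondary peak near
the most negative real parts. evospectra is a simulator and analysis
toolkit for studying exactly this contrast. It is aimed at theoretical
ecologists and complex-systems researchers who want to generate evolved
webs, inspect their spectra, and compare them against a
connectivity-matched random-matrix null.

## Model

One basic nutrient source, `n1` primary producers, `n − n1` consumers,
Holling type-I interactions:

```
producers:  Ṡ_i/S_i = k (1 − Σ_{j∈prod} S_j) − α_i − Σ_k η_ki S_k
consumers:  Ṡ_k/S_k = Σ_m β η_km S_m − α_k − Σ_p η_pk S_p
```

Webs grow by sequential invasion: a random species (`α ~ U(0.05, 0.5)`,
`η ~ U(0.01, 1)`, initial biomass `1e-10`) enters, the system relaxes
(adaptive Runge–Kutta with extinction-event detection, extinction
threshold `1e-12`), extinct species are removed, and the next attempt
starts from the new feasible state. Three assembly modes control loop
structure: `treelike` (single-resource consumers), `non_omnivorous`
(second resource only at equal trophic level) and `omnivorous` (second
resource at any level). The fixed point solves `R S* = K`; the
community matrix is the Jacobian `C = diag(S*) ∂f/∂S` at `S*`, and its
eigenvalues decide linear stability. The null model draws matrices with
diagonal −1 and off-diagonal `N(0, 1)` entries present with probability
`p(N) = (N² + 21N − 28)/(9N(N − 1))`.

See `docs/methods.md` for the full protocol, tolerances and design
choices.

## Worked example

```python
from evospectra import AssemblyConfig, evolve, metrics, success_rate

history = evolve(AssemblyConfig(mode="treelike", beta=0.75, attempts=2000, seed=42))
print(f"success rate: {success_rate(history):.3f}")
print({r: round(f, 3) for r, f in sorted(metrics(history)["richness_histogram"].items())})
```

prints

```
success rate: 0.141
{1: 0.013, 2: 0.022, 3: 0.14, 4: 0.041, 5: 0.213, 6: 0.04, 7: 0.247, 8: 0.025, 9: 0.154, 10: 0.003, 11: 0.102}
```

14 % of the 2000 invaders established (the rate declines toward ~11.5 %
in longer runs as the web accumulates intrinsically fit species), and
the web spends most of its history at odd species richness — webs whose
species can be paired up with the nutrient source are the ones that
admit feasible steady states, and the nutrient participates in such a
pairing only at odd richness.

The `examples/` directory holds one short script per capability:
two-species closed-form theory (`two_species_theory.py`), full assembly
runs (`assemble_food_web.py`) and the evolved-versus-random spectral
contrast (`spectra_vs_random.py`). A thin CLI mirrors the library:

```
evospectra evolve --mode omnivorous --beta 0.75 --attempts 10000 --seed 1 --out run/
evospectra random --n 5 --samples 10000 --seed 1 --out rnd/
evospectra analyze --in run/eigenvalues.csv --richness 5 --out analysis/
```

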