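# fretfluor

Simulation and analysis of single-molecule FRET-barcode ("FRETfluor")
measurements in a feedback trap.

FRETfluors are small DNA-scaffolded labels carrying a Cy3/Cy5 donor-acceptor
pair. Changing the dye spacing (and local attachment chemistry) tunes the
FRET efficiency, which simultaneously shifts three spectroscopic observables
of the donor-excited molecule:

- **green (donor) brightness** — proportional to `1 − E`,
- **red (acceptor) brightness** — proportional to `E`,
- **donor fluorescence lifetime** — `τ = τ₀ (1 − E)`.

A feedback trap (an ABEL-type electrokinetic trap) holds one freely diffusing
molecule in solution for seconds while time-correlated single-photon counting
records every photon in four channels (green/red × two polarizations). Each
trapped molecule therefore yields a multi-parameter *signature*
`(green brightness, red brightness, lifetime)` that identifies which barcode
it is — many distinguishable labels from a single excitation/emission band.
Because the trap also tracks the molecule's position, the same measurement
reports its diffusion: a barcode bound to a larger target is confined more
tightly, so binding is read out without washing.

This package implements the full chain:

1. **Registry** (`fretfluor.registry`) — construct families and their
   photophysics; FRET predicted from dye spacing via
   `E = 1 / (1 + (N·rise/R₀)⁶)`; sample-mixture arithmetic.
2. **Photon simulator** (`fretfluor.photon_sim`) — synthetic photon streams
   with Poisson trapping events, per-channel backgrounds, TCSPC microtimes
   (IRF-convolved), acceptor bleaching/blinking, and feedback-trap
   position trajectories. This is first-class, tested code: every analysis
   stage is validated against it.
3. **Segmentation** (`fretfluor.segmentation`) — background estimation and
   photon-by-photon change-point detection (maximum-likelihood rate-step
   test with Monte-Carlo-calibrated critical values), producing
   constant-brightness *levels*.
4. **Level statistics** (`fretfluor.level_stats`) — background-subtracted
   brightness, FRET efficiency, and IRF-reconvolution maximum-likelihood
   lifetime per level; positional confinement per 1000-photon group.
5. **Classification** (`fretfluor.classify`) — K-means clustering of level
   signatures, axis-aligned Gaussian cluster models with outlier rejection,
   Monte-Carlo pairwise misclassification probabilities, and exact
   maximum-clique selection of mutually distinguishable label palettes.
6. **Binding** (`fretfluor.binding`) — diffusion estimation from
   feedback-corrected increments and two-component confinement clustering
   into bound/unbound populations with Wilson confidence intervals.
7. **Pipeline & CLI** (`fretfluor.pipeline`, `fretfluor` command) — a fixed
   stage order with deterministic seeding, a manifest, and TSV/YAML reports.

## Worked example

Simulate a 60 s acquisition of a two-construct mixture (AB10 and AB16, half
of the molecules carrying a bound target) and run the full analysis:

```python
from fretfluor import SimConfig
from fretfluor.pipeline import RunConfig, run_pipeline

config = RunConfig(
    sim=SimConfig(
        mixture=[("AB10", 0.5), ("AB16", 0.5)],
        total_duration=60.0,     # s
        seed=21,
        event_rate=0.6,          # trapping events / s
        dwell_mean=0.8,          # s in the trap
        bound_fraction=0.5,      # half the molecules carry a bound target
    ),
    classify_K=2,
    n_mc=5000,
    seed=0,
)
result = run_pipeline(config)

print(result.manifest["counts"])
cols = ["green_b", "red_b", "tau_ns", "n_photons", "duration_ms"]
print(result.signature_frame[cols].round(3).head(6))
print("compatible palette:", result.subset.labels,
      "max pairwise confusion:", round(result.subset.certificate, 4))
print(result.binding_report.round(3))
```

Output:

```
{'photons': 634290, 'change_points': 61, 'candidate_levels': 62,
 'retained_levels': 20, 'clusters': 2, 'confinement_points': 508}
   green_b  red_b  tau_ns  n_photons  duration_ms
0    0.159  0.153   0.818      31166      937.753
1    0.017  0.288   0.075       6277      193.195
2    0.019  0.294   0.095      12642      380.608
3    0.020  0.291   0.104      14861      449.624
4    0.019  0.295   0.100      69221     2074.248
5    0.021  0.287   0.120       8173      249.574
compatible palette: ['0', '1'] max pairwise confusion: 0.0
  label  n_bound  n_unbound  n_ambiguous  fraction_bound  ci_lo  ci_hi
0     0      182        110            0           0.623  0.566  0.677
1     1      159         57            0           0.736  0.674  0.790
```

The two constructs separate cleanly: AB16 levels sit at
`(green ≈ 0.159, red ≈ 0.153, τ ≈ 0.82 ns)` and AB10 levels at
`(green ≈ 0.02, red ≈ 0.29, τ ≈ 0.1 ns)` — exactly the
`(B₀(1−E), B₀E, τ₀(1−E))` signatures predicted by the registry. The
`fraction_bound` values are per 1000-photon confinement group; checked
against the simulator's ground truth, every one of the 508 bound/unbound
calls in this run is correct (this particular 60 s draw contains 26
trapping events of which 58 % are bound, and bound events happen to
contribute more photon groups).

The same run from the command line:

```sh
fretfluor analyse --config run.yaml --out report/
# report/: levels.tsv signatures.tsv confusion_matrix.tsv subset.yaml
#          binding.tsv manifest.yaml
```

Other subcommands: `fretfluor simulate` (write a synthetic stream to
HDF5/CSV), `fretfluor design-palette` (confusion matrix and largest
mutually distinguishable construct subset), `fretfluor accuracy-curve`
(identification rate versus photons per level).

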