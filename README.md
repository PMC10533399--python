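# batcolony

Analysis pipeline for collective spatial behaviour and hippocampal activity
in groups of freely flying bats — with a synthetic-session generator that
provides ground truth for every stage.

Groups of echolocating fruit bats in a flight room organise themselves
around a handful of self-selected rest sites: each bat alternates long rests
with short flights (~77 flights per hour) along repeatable paths, lands
either next to a conspecific ("social" flight, nearest-neighbour distance
< 0.6 m at landing) or on an empty spot ("non-social", > 0.9 m), and
broadcasts paired echolocation clicks around take-off and landing.
`batcolony` implements the full analysis chain for such experiments:

- **tracking** — position smoothing (local quadratic regression + rest
  median), flight segmentation (0.5 m/s threshold), agglomerative rest-site
  clustering (0.2 m linkage, 10 s minimum occupancy), occupancy maps;
- **group_state** — group-configuration state space (Sammon embedding,
  possible/visited/frequent state counts) and pairwise proximity indexes
  with circular-time-shift nulls;
- **spatial** — 2D and flight-path (1D) firing-rate maps, Skaggs spatial
  information SI = Σᵢ (pᵢλᵢ/λ̄) log₂(λᵢ/λ̄), circular spike-shuffle
  significance, discrete-Fréchet path clustering, split-half stability, and
  Gaussian place-field fitting;
- **stats** — the exact conditional test for two Poisson rates (binomial
  conditional on the total count), label-permutation tests, circular-shift
  nulls;
- **social** — three complementary tests of social modulation of firing
  around take-off/landing (stepwise Poisson GLM; anchored firing difference
  with positional permutation control; conservative 5-vs-5 subsample
  modulation scores for firing/position/heading/acceleration), target-bat
  identity analysis, object controls, reward controls;
- **others** — responses of a stationary bat to others' take-offs
  (low-mobility event selection via the on-board accelerometer, window-wise
  signed-rank PSTH significance, response magnitudes, sparseness-style
  selectivity indexes);
- **echo** — ultrasonic click detection (10–40 kHz band, 10 sd peaks) and
  spectral classification (k-means on power-spectrum principal components);
- **population** — ROI-ensemble analyses (normalized rates, per-ROI
  permutation tests, PCA separation, cross-validated logistic/SVM decoding,
  anatomical clustering test);
- **synthetic** — generates complete sessions with known ground truth,
  including spike trains from the spatial/social/conjunctive cell model

      λ(tᵢ) = λ_spont + w(tᵢ)·λ_c·exp(−|x(tᵢ)−x_c|²/2σ_c²)
                       + b(tᵢ)·λ_s·exp(−(tᵢ−t_s)²/2σ_s²)

  simulated as an inhomogeneous Poisson process on 200 ms bins, plus 8 Hz
  wingbeat accelerometer signatures and paired echolocation clicks.

## Worked example

Simulate one hour of a five-bat group, plant a place cell on the focal
bat's most common flight path, and recover its field:

```python
import numpy as np
from collections import Counter
import batcolony as bc
from batcolony import spatial, tracking

cfg = bc.SessionConfig(n_bats=5, duration=3600.0, seed=1)
session = bc.generate_group_session(cfg)
track = tracking.smooth_positions(session.tracks[0])

pairs = [sp for f, sp in zip(session.flights, session.truth["flight_site_pair"])
         if f.bat_id == 0]
common = Counter(pairs).most_common(1)[0][0]
path = [f for f, sp in zip(session.flights_of(0), pairs) if sp == common]
centre = path[0].path[len(path[0].path) // 2][:2]

cell = bc.CellSpec("spatial", lam_spont=0.4, lam_c=8.0, x_c=tuple(centre),
                   sigma_c=0.5)
spikes = bc.sample_spikes(bc.simulate_cell_rate(session, cell, 0), seed=2)
rmap = spatial.rate_map_2d(track, spikes)
fit = spatial.fit_gaussian_field(rmap)
print(f"flights: {len(session.flights)}  spikes: {len(spikes)}")
print(f"amplitude {fit['amplitude']:.2f} Hz  sigma {fit['sigma']:.2f} m  "
      f"centre error {np.linalg.norm(fit['centre'] - centre):.3f} m")
```

Output:

```
flights: 353  spikes: 1776
amplitude 7.53 Hz  sigma 0.50 m  centre error 0.049 m
```

The fitted amplitude estimates the cell's generative field peak above its
0.4 Hz baseline (true value 8 Hz); the centre lands within a few
centimetres of the planted field centre.

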