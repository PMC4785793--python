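"""Classify a dimer movie into V/O/B/P states and summarise its dynamics.

Generates a synthetic movie (Markov state process + worm-like-chain arms +
localisation noise), classifies every frame from its landmark geometry,
and prints class frequencies, transition counts and the Gaussian fit of
the engaged head-hinge distance peak.
"""

import numpy as np

from smcflex import (
    MissingLandmarkError,
    SynthConfig,
    annotate_movie,
    gaussian_peak,
    generate_movie,
    head_hinge_distances,
    hinge_angle,
)

config = SynthConfig(n_frames=400, seed=3)
frames, truth = generate_movie(config)
annotation = annotate_movie(frames)

accuracy = np.mean(
    [lab is e.state for (_, lab), e in zip(annotation.labels, truth.entries)]
)
print("class frequencies (fraction of classified frames):")
for label, frac in sorted(annotation.class_frequencies.items()):
    print(f"  {label.value}: {frac:.3f}")
print(f"agreement with generator ground truth: {accuracy:.1%}")

print("transitions between consecutive frames:")
for (a, b), count in sorted(annotation.transition_counts.items()):
    if a is not b:
        print(f"  {a.value} -> {b.value}: {count}")

hinge_dists = []
for f in frames:
    try:
        hinge_dists.extend(head_hinge_distances(f))
    except MissingLandmarkError:
        pass
mu, sd = gaussian_peak(hinge_dists, (0.0, 10.0))
print(f"engaged head-hinge peak: {mu:.2f} +/- {sd:.2f} nm (Gaussian fit, [0, 10] nm window)")

angles = [hinge_angle(f) for f in frames[:200]]
print(f"median hinge opening angle: {np.median(angles):.0f} degrees")
print()
print("Engaged-state geometry concentrates a few nanometres from the hinge;")
print("the broad angle distribution reflects the high flexibility of the arms.")
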