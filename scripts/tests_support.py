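"""Small helpers shared by the acceptance script."""

from mlpi.features import Sample


def make_samples(rng, n, labeled, n_channels=2, patient_id="p"):
    """Random toy samples with Gaussian image features and uniform PI/labels."""
    out = []
    for _ in range(n):
        out.append(Sample(
            z=tuple(float(v) for v in rng.normal(size=n_channels)),
            pi=float(rng.uniform()),
            patient_id=patient_id,
            location=(0, 0),
            y=float(rng.uniform()) if labeled else None,
        ))
    return out
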