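import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cnapipe as cp

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_layout():
    return cp.make_genome(n_chromosomes=4, chrom_length=20_000_000,
                          probes_per_chromosome=80, seed=1)


@pytest.fixture(scope="session")
def small_cohort(small_layout):
    """Three low-noise samples run through segmentation + estimation + calling.

    Session-scoped because CBS dominates the cost; tests must not mutate it.
    """
    layout = small_layout
    spec = cp.AberrationSpec(n_gains=2, n_losses=2, n_hd=1, n_amplicons=1,
                             gain_length=(10, 25), loss_length=(10, 25),
                             hd_length=(4, 8), amplicon_length=(5, 12))
    out = []
    for k, purity in enumerate((1.0, 0.9, 0.85)):
        truth = cp.simulate_truth(layout, spec, purity=purity,
                                  target_ploidy=2, seed=40 + k)
        prof = cp.render_ratios(truth, layout, cp.NoiseModel(sd=0.05, seed=50 + k),
                                sample_id=f"s{k}")
        seg = cp.segment_profile(prof, cp.SegmentationConfig(seed=60 + k))
        model = cp.fit_tumor_model(seg)
        cn = cp.assign_copy_numbers(
            seg, model, prof.data[["chromosome", "start", "end", "probe_id"]])
        call = cp.call_probes(cn)
        out.append({"truth": truth, "ratios": prof, "segments": seg,
                    "cn": cn, "call": call})
    return out


@pytest.fixture(scope="session")
def unit_probe_calls():
    """Builder for toy call sets on a unit-spaced probe grid."""
    import pandas as pd
    from cnapipe.aberration import AberrationCall, NEUTRAL

    def build(n_probes, aberrant, cls, chromosome="chr1", sample_id="t"):
        classes = np.array([NEUTRAL] * n_probes, dtype=object)
        for a, b in aberrant:
            classes[a:b] = cls
        probes = pd.DataFrame({
            "chromosome": chromosome,
            "start": np.arange(n_probes),
            "end": np.arange(n_probes) + 1,
            "probe_id": [f"p{i}" for i in range(n_probes)],
            "copy_number": 2,
            "class": classes,
        })
        return AberrationCall(sample_id=sample_id, probes=probes)

    return build
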