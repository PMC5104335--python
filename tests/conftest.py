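import numpy as np
import pandas as pd
import pytest

from somhub import synthetic as syn
from somhub.io_formats import ExpressionMatrix, Pwm, SampleDescriptor, TIMEPOINTS


@pytest.fixture(scope="session")
def small_dataset():
    """Shared synthetic dataset: one module + two KO effects."""
    config = syn.SimulationConfig(
        n_genes=150,
        n_negative_controls=20,
        modules=(syn.ModuleSpec(20, 0.95, 0.5),),
        ko_effects=(
            syn.KoEffect("G00050", "P7", 2.0),
            syn.KoEffect("G00060", "P14", 0.4),
        ),
        seed=11,
    )
    matrices, annotation, truth = syn.generate_expression(config)
    return config, matrices, annotation, truth


@pytest.fixture(scope="session")
def strong_pwm():
    """8-long near-consensus PWM used by motif tests."""
    probs = np.full((4, 8), 0.04)
    for j, c in enumerate([0, 1, 2, 3, 0, 1, 2, 0]):
        probs[c, j] = 0.88
    return Pwm("TEST_MOTIF", probs)


def make_matrix(values, row_ids=None, genotypes=("control",), n_reps=3):
    """ExpressionMatrix with the standard 5-timepoint layout."""
    values = np.asarray(values, dtype=float)
    samples = [
        SampleDescriptor(f"{g}_{tp}_r{r}", g, tp, r)
        for g in genotypes
        for tp in TIMEPOINTS
        for r in range(1, n_reps + 1)
    ]
    if row_ids is None:
        row_ids = [f"R{i:03d}" for i in range(values.shape[0])]
    frame = pd.DataFrame(values, index=row_ids, columns=[s.sample_id for s in samples])
    return ExpressionMatrix(frame, samples)
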