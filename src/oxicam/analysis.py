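"""Channel-weight visualization experiment.

Trains many instances of the linear-mix regressor (a single linear channel
combination layer followed by convolutional feature extraction) that
differ only in their random initialization, then collects the first-layer
RGB weight directions.  Mirroring the study design, every instance is
trained on the pooled recordings of several participants (cycles 1-2) and
tagged with its correlation on the held-out third cycles: pooling
participants with different skin tones (baseline reflectance) is what
forces the learned combination toward the channels that actually carry
oxygenation information — red and blue, where oxygenated and deoxygenated
hemoglobin differ in light extinction — rather than a participant-specific
pulse-cancellation direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .experiments import build_recording_segments
from .models import ModelConfig, build_model
from .preprocessing import SegmentSet, segments_in_interval, standardize_segments
from .synthetic import generate_cohort
from .training import OptimizerParams, extract_channel_weights, train_model

__all__ = ["train_linear_mix_instances", "LINEAR_MIX_VIZ_CONFIG"]

# A lighter conv stack than the full regressor: the visualization
# experiment only needs an amplitude-sensitive readout after the linear mix.
LINEAR_MIX_VIZ_CONFIG = ModelConfig(
    variant="model1",
    ablation="linear_mix",
    conv_filter_counts=(8, 4),
    dense_widths=(32,),
)


def train_linear_mix_instances(
    n_instances: int = 20,
    n_subjects: int = 5,
    epochs: int = 40,
    stride_s: float = 1.5,
    lr: float = 3e-3,
    cohort_seed: int = 0,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Train linear-mix model instances and return their weight directions.

    All instances share one cohort and one train/validation split (cycles
    1-2 of every recording pooled for training, cycle 3 for validation and
    the correlation tag); only the initialization/shuffling seed varies.
    The epoch budget and learning rate default to values at which the
    mixing layer itself converges (the layer receives weak gradients, so
    short runs would report near-initialization directions).
    """
    cfg = config or LINEAR_MIX_VIZ_CONFIG
    cohort = generate_cohort(n_subjects, 1, ("PU",), seed=cohort_seed)
    train_sets, val_sets = [], []
    for rec in cohort:
        segs = build_recording_segments(rec, stride_s=stride_s)
        cb = rec.cycle_bounds
        train_sets.append(segs.subset(segments_in_interval(segs, [(cb[0][0], cb[1][1])])))
        val_sets.append(segs.subset(segments_in_interval(segs, [(cb[2][0], cb[2][1])])))
    train = SegmentSet.concatenate(train_sets)
    val = SegmentSet.concatenate(val_sets)
    (train_std, val_std), _ = standardize_segments(train, val)

    opt = OptimizerParams(lr=lr, max_epochs=epochs, patience=epochs)
    ss = np.random.SeedSequence(seed)
    models, rhos = [], []
    for _ in range(n_instances):
        inst_seed = int(np.random.default_rng(ss.spawn(1)[0]).integers(0, 2**31 - 1))
        model = build_model(cfg, seed=inst_seed)
        train_model(model, train_std, val_std, opt, seed=inst_seed)
        # tag with the held-out-cycle correlation of window-level predictions
        pred = model.predict(val_std.X)
        if np.ptp(pred) < 1e-9:
            rho = np.nan
        else:
            rho = float(stats.pearsonr(pred, val_std.labels).statistic)
        models.append(model)
        rhos.append(rho)
    return extract_channel_weights(models, rhos)
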