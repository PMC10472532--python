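"""Train a channel-combination CNN on one synthetic participant.

Session 1 of the participant provides training (breath cycles 1-2) and
validation (cycle 3); session 2 is held out entirely.  The trained model
predicts a 5 Hz SpO2 trace for the test session, which is clipped at 100%
and smoothed with the 10-s moving average before scoring.
"""

from oxicam.experiments import build_recording_segments
from oxicam.models import ModelConfig, build_model
from oxicam.preprocessing import (
    interpolate_reference,
    oversample_balanced,
    segments_in_interval,
    standardize_segments,
)
from oxicam.synthetic import generate_cohort
from oxicam.training import (
    OptimizerParams,
    compute_metrics,
    predict_trace,
    train_model,
)

cohort = generate_cohort(1, 2, ("PU",), seed=3)
train_rec, test_rec = cohort

segs = build_recording_segments(train_rec, stride_s=0.2)
cb = train_rec.cycle_bounds
train = segs.subset(segments_in_interval(segs, [(cb[0][0], cb[1][1])]))
val = segs.subset(segments_in_interval(segs, [(cb[2][0], cb[2][1])]))
train = oversample_balanced(train, 512, seed=0)
(train_std, val_std), scaler = standardize_segments(train, val)

config = ModelConfig(variant="model1", dropout_p=0.3, batchnorm=True)
model = build_model(config, seed=1)
print(f"{model.name}: {model.n_params} trainable parameters")

state = train_model(
    model, train_std, val_std,
    OptimizerParams(lr=1e-3, max_epochs=40, patience=40), seed=1,
)
print(f"best validation RMSE {state.best_val_loss:.2f} % at epoch {state.best_epoch}")

pred = predict_trace(model, test_rec, scaler)
ref5 = interpolate_reference(test_rec.reference)
rho, mae, rmse = compute_metrics(pred, ref5)
print(f"held-out session: rho = {rho:.3f}, MAE = {mae:.2f} %, RMSE = {rmse:.2f} %")
# rho tracks whether the prediction follows the breath-hold desaturation
# dips; MAE/RMSE measure the absolute error in percentage points.
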