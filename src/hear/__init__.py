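"""hear — hierarchical ensemble activity recognition for wearable IMU data.

Classifies everyday activities from multi-sensor inertial recordings
(3-axis acceleration, angular velocity and angle per sensor) using
wavelet-smoothed sliding windows, per-channel LSTM + 1-D CNN extractors,
per-sensor and cross-sensor 2-D CNN fusion, and focal loss to counter
class imbalance.
"""

from .data import (
    CHANNEL_NAMES,
    NormStats,
    SensorSample,
    SensorStream,
    Window,
    WindowedDataset,
    normalize,
    read_csv,
    segment_windows,
    synchronize,
    write_csv,
)
from .estimators import (
    HierarchicalEnsembleClassifier,
    WaveletSmoother,
    WindowNormalizer,
)
from .experiments import ExperimentConfig, compare_losses, gamma_sweep
from .generate import (
    ACTIVITY_NAMES,
    ActivityProfile,
    Scenario,
    generate_dataset,
    make_profiles,
    scenario,
)
from .losses import LossConfig, cross_entropy, focal_loss, loss_and_grad_logits
from .nn import Adam, HierarchicalNetwork, NetworkSpec, build_model, count_parameters
from .train import (
    EvaluationReport,
    TrainConfig,
    evaluate,
    metrics_from_confusion,
    split_holdout,
    train,
)
from .wavelet import WaveletConfig, approx_length, smooth_dataset, smooth_window

__version__ = "0.1.0"
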