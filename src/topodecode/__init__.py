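"""Topography-preserving decoding of movement components from EEG.

The package covers the full experimental loop on synthetic data:
simulation of multi-subject reaching experiments with planted
movement-related cortical potentials (`topodecode.synth`),
preprocessing and labelling (`topodecode.preprocess`), the 13x9
topography-preserving input representation (`topodecode.topomap`), ERP
cluster statistics and MRCP analysis (`topodecode.erpstats`), the
5-layer spatiotemporal convolutional decoder (`topodecode.cnn3d`),
validation protocols (`topodecode.evalsuite`) and gradient-weighted
class activation maps (`topodecode.gradcam`).
"""

from .layout import SensorLayout, biosemi128_layout
from .synth import (
    SimulationConfig,
    RTDistribution,
    SubjectRecording,
    KinematicsTrace,
    simulate_subject,
    simulate_experiment,
    mrcp_waveform,
    spatial_pattern,
    background_and_artifacts,
    draw_trial_kinematics,
)
from .preprocess import (
    PreprocConfig,
    LabelledEpochSet,
    bandpass,
    ica_clean,
    compute_and_label_rt,
    epoch_normalize_resample,
    build_datasets,
    preprocess_subject,
)
from .topomap import (
    GridMapping,
    TopoTensorSet,
    default_biosemi128_mapping,
    derive_grid_mapping,
    apply_mapping,
    inverse_mapping,
    adjacency,
    grid_adjacency,
)
from .erpstats import ClusterTestResult, MRCPResult, cluster_test, mrcp, baseline_logistic
from .cnn3d import (
    ArchitectureSpec,
    TrainingConfig,
    TrainedModel,
    build_model,
    build_model_2d,
    train,
    predict,
)
from .evalsuite import EvalReport, loso, split_eval, metrics
from .gradcam import ActivationMap, grad_cam, average_maps, localization_score
from .containers import save_recording, load_recording, save_epochs, load_epochs

__version__ = "0.1.0"
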