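"""Consensus self-organizing maps for multi-class classification of
imbalanced data.

The package trains toroidal SOMs, turns the occupied lattice into a full
class-probability surface by wavefront expansion, stabilizes the surface
with consensus priors from repeated runs, and gates predictions on a
confidence threshold so dubious queries come back as explicitly
non-conclusive instead of misclassified. Resampling (SMOTE, random
undersampling), imbalance-aware metrics, k-NN baselines and a stratified
cross-validation harness round out the evaluation protocol.
"""

from importlib import resources
from typing import Dict, List

from .consensus import (
    NON_CONCLUSIVE,
    CsomModel,
    Prediction,
    PriorTable,
    ProbabilityMap,
    consensus_priors,
    expand_probabilities,
    fit_csom,
    moore_neighbors,
    predict,
    predict_batch,
)
from .data import (
    ClassSpec,
    CorrelationTable,
    LabelledDataset,
    NON_SUBSTRATE,
    SynthSpec,
    generate_imbalanced,
    label_substrates,
    read_correlations,
    read_keel,
    read_table,
    three_class_benchmark,
    write_table,
)
from .evaluation import (
    CvResult,
    PairedTestResult,
    cross_validate,
    knn_classify,
    knn_classify_batch,
    paired_t_test,
    stratified_kfold,
)
from .features import (
    FeatureTable,
    ReducerModel,
    SigmoidScaler,
    apply_reducer,
    fit_reducer,
    prune_correlated,
    sigmoid_scale,
)
from .imbalance import (
    ConfusionResult,
    MetricsReport,
    balanced_target_counts,
    compute_metrics,
    random_undersample,
    smote,
    tally,
)
from .io import export_map_csv, load_model, save_model
from .som import (
    Coordinate,
    OccupancyMap,
    SomConfig,
    SomGrid,
    find_bmu,
    init_grid,
    project,
    quantization_error,
    torus_distance,
    train_som,
)

__version__ = "0.1.0"


def descriptor_sets() -> Dict[str, List[str]]:
    """The bundled named descriptor sets (P-gp, MRP1, BCRP, DD17).

    Use with :meth:`FeatureTable.select` to pick a model's columns by name.
    """
    text = (
        resources.files("csom") / "data_tables" / "descriptor_sets.txt"
    ).read_text()
    sets: Dict[str, List[str]] = {}
    current = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sets[current] = []
        elif current is not None:
            sets[current].append(line)
    return sets
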