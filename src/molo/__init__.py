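"""molo: repopulation-weighted single-cell analysis of sorted stem cells.

Identifies the molecularly overlapping (MolO) subpopulation shared across
heterogeneous HSC sorting strategies from single-cell qPCR, transfers a
MolO score to single-cell RNA-seq with a random-forest classifier, derives
score-correlated gene signatures, and links index-sort surface phenotype
to single-cell functional outcomes via the SuMO score and limiting-dilution
frequency estimation.
"""

from .embedding import Embedding2D, embed_tsne
from .function_link import (
    LDAResult,
    MammaryResult,
    RepopulationCall,
    SuMOScore,
    call_repopulation,
    calls_to_frame,
    fit_sumo_axis,
    joint_marker_embedding,
    limiting_dilution,
    mammary_pipeline,
    region_enrichment,
    ward_partition,
)
from .io_core import (
    CountsMatrix,
    CtMatrix,
    IndexSortTable,
    PipelineConfig,
    RunManifest,
    TransplantRecord,
    configure_logging,
    read_counts,
    read_ct_table,
    read_index_table,
    read_transplant_table,
    write_counts,
    write_ct_table,
    write_index_table,
    write_transplant_table,
)
from .molo_classifier import (
    CVResult,
    MolOClassifier,
    MolOScore,
    crossvalidate,
    platform_features,
    score_cells,
    train_molo_classifier,
)
from .molo_finder import (
    MarkerEnrichment,
    MolOAssignment,
    WeightVector,
    identify_molo,
    index_marker_enrichment,
    jensen_shannon,
    molo_differential_genes,
    neighborhood_composition,
)
from .qpcr_panel import (
    ClusterResult,
    DeltaCtMatrix,
    apply_gene_exclusions,
    delta_ct_normalize,
    hierarchical_cluster,
    spearman_distance_matrix,
)
from .scrnaseq_hvg import (
    GeneSignature,
    NoiseFit,
    PCAResult,
    SizeFactors,
    call_variable_genes,
    correlate_genes_with_score,
    fit_technical_noise,
    normalized_expression,
    pca_cells,
    size_factors,
)
from .stats_utils import benjamini_hochberg, spearman_test
from .synthetic_data import (
    EXCLUDED_GENES,
    HOUSEKEEPERS,
    INDEX_CHANNELS,
    MAMMARY_CHANNELS,
    PANEL_GENES,
    SimSpec,
    simulate_cell_truth,
    simulate_colonies,
    simulate_counts,
    simulate_index,
    simulate_index_and_function,
    simulate_qpcr,
    simulate_transplants,
)

__version__ = "0.1.0"


def run_cli(argv):
    """CLI entry point (lazy import to avoid a circular dependency)."""
    from .cli import run_cli as _run

    return _run(argv)
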