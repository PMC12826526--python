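"""looplink: loop-based structural analysis of cross-linking MS data.

The pipeline: parse cross-link identification tables into canonical
residue-pair sets (`xl_io`), build residue-level structural networks
(`netbuild`), extract the overlapping loop clustering every cross-link
induces (`loopclust`), and compare protein states by element-centric
similarity (`ecs`).  Replicate saturation, subsample-similarity and
leave-one-out analyses live in `sampling`; atomic-structure mapping and
3D network embedding in `structmap`; a ground-truth synthetic study
generator in `synthdata`.
"""

from importlib import resources

from .ecs import ECSConfig, ECSResult, ecs_compare, element_affinities
from .loopclust import Loop, LoopClustering, extract_loops
from .netbuild import (
    DSBU_SPAN,
    BACKBONE_SPACING,
    NetworkConfig,
    StructuralNetwork,
    build_network,
    export_gml,
    import_gml,
)
from .sampling import (
    AccumulationCurve,
    LOOResult,
    NullModelConfig,
    ReplicateSeries,
    SimilarityCurve,
    detect_divergence_threshold,
    empirical_accumulation,
    expected_null_accumulation,
    loo_analysis,
    null_accumulation,
    subsample_similarity,
)
from .structmap import (
    DistanceConstraint,
    DistanceStats,
    LayoutConfig,
    RgSimConfig,
    RgSimResult,
    StructureModel,
    distance_stats,
    layout3d,
    map_constraints,
    radius_of_gyration,
    read_calpha,
    simulate_rg,
)
from .synthdata import (
    DetectionModel,
    SyntheticConformer,
    SyntheticStudy,
    generate_chain,
    generate_two_state_study,
    observable_pairs,
    perturb_segment,
    sample_replicates,
)
from .xl_io import (
    CrossLinkRecord,
    CrossLinkSet,
    ProteinSequence,
    SiteSet,
    TableSchema,
    count_possible_pairs,
    enumerate_sites,
    merge_crosslink_sets,
    read_fasta,
    read_xl_table,
    to_crosslink_set,
)

__version__ = "0.1.0"


def bundled_fasta(name: str):
    """Path to a bundled reference FASTA (``tau_2n4r`` or ``myoglobin_horse``)."""
    return resources.files("looplink.data") / f"{name}.fasta"
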