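"""ethoseq: behavioral sequence analysis of dyadic agonistic encounters.

From ethogram-coded event logs to first-order transition matrices,
quasi-independence log-linear inference with Freeman-Tukey deviates,
kinematic diagrams, nonparametric ontogeny/dominance/escalation
statistics, and a semi-Markov encounter simulator.
"""

from importlib import resources as _resources

from .ethogram import (
    Behavior,
    Category,
    Ethogram,
    collapse_low_intensity,
    default_ethogram,
    load_ethogram,
)
from .events import (
    EventLog,
    EventRecord,
    TimeBudget,
    bout_durations,
    interval_counts,
    make_event_log,
    occurrence_rate,
    read_event_log,
    time_budget,
    write_event_log,
)
from .transitions import (
    TransitionCounts,
    build_transition_counts,
    extract_sequence,
    read_transition_matrix,
    write_transition_matrix,
)
from .quasi_independence import (
    CohortSet,
    QuasiIndependence,
    QuasiIndependenceResults,
    classify_hi_involvement,
    cohort_persistence_classes,
    fit_quasi_independence,
    freeman_tukey_deviates,
    g_statistic,
    homogeneity_across_ages,
    marginal_by_age_test,
    significance_criterion,
)
from .ontogeny import (
    GroupedSamples,
    PairRetreatRecord,
    arcsine_proportion_comparisons,
    dominance_test,
    dunn_posthoc,
    escalation_test,
    kruskal_wallis,
    pair_split_records,
)
from .kinematics import build_diagram, edge_band, export_dot, node_size_class
from .synthetic import SynthConfig, default_parameters, generate_cohort, generate_session

__version__ = "0.1.0"

#: ages (days post-eclosion) of the five study cohorts
STUDY_AGES = (1, 2, 3, 4, 6)


def packaged_matrix_path(age_days: int):
    """Path to a packaged cohort transition-matrix fixture.

    The day-3 matrix is the study's printed table; the other cohorts'
    matrices were never deposited, so the packaged day-1/2/4/6 files are
    synthetic reconstructions (see their filenames) engineered to carry
    the published significance structure.
    """
    if age_days == 3:
        name = "transitions_day3.tsv"
        ref = _resources.files("ethoseq.data").joinpath(name)
    elif age_days in (1, 2, 4, 6):
        name = f"transitions_day{age_days}_synthetic.tsv"
        ref = _resources.files("ethoseq.data").joinpath("synthetic", name)
    else:
        raise ValueError(f"no packaged matrix for age {age_days}")
    return ref
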