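"""paleochron: Bayesian radiocarbon chronologies for fossil collection units."""

from importlib import resources as _resources

from .calibration import (
    CalibratedDensity,
    CalibrationCurve,
    ChronControl,
    GeochronDate,
    calendar_density,
    calibrate_radiocarbon,
    density_quantile,
    load_calibration_curve,
    summarize_control,
)
from .chronology_builder import (
    Chronology,
    SampleAge,
    bounds_sample_ages,
    collection_age_bounds,
    event_sample_ages,
    time_interval_label,
)
from .neotoma_io import (
    emit_oxcal_script,
    filter_geochron_dates,
    read_collection,
    select_collection,
    write_chronology_tables,
)
from .phase_model import (
    PhaseSpec,
    PosteriorSamples,
    SequenceSpec,
    build_collection_model,
    convergence_diagnostics,
    infer_order,
    log_posterior_density,
    sample_posterior,
)
from .pipeline import build_collection_chronologies
from .strat_inference import classify_undated_unit, infer_all_undated, infer_undated_range
from .synthetic_data import make_curve, scenario_fixtures, simulate_collection
from .units import AnalysisUnit, CollectionUnit

__version__ = "0.1.0"


def intcal20_path() -> str:
    """Filesystem path of the bundled IntCal20 curve file."""
    return str(_resources.files("paleochron").joinpath("data/intcal20.14c"))


def load_intcal20(resolution: int = 1) -> CalibrationCurve:
    """Load the bundled IntCal20 curve (0-55,000 cal BP)."""
    return load_calibration_curve(intcal20_path(), resolution=resolution, name="intcal20")
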