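"""tailend: 3'-end profiling of ultrashort RNAs from tailed RNA-seq libraries.

Resolves single-nucleotide 3'-end length distributions of very short RNAs
(e.g. bacterial 6S RNA product RNAs) from libraries built by 3'-homo-
nucleotide tailing: tail-signature trimming, anchored exact mapping, and
the four-case merge of two differently-tailed libraries, plus a
deterministic library simulator and a synthetic read generator.
"""

from importlib import resources as _resources

from .io import (
    CountTable,
    ParseError,
    SeqRecord,
    read_config,
    read_count_table,
    read_fasta,
    read_fastq,
    write_count_table,
    write_fastq,
)
from .trim import (
    AdapterSpec,
    SelectionStats,
    TailSpec,
    TrimOutcome,
    find_tail_start,
    selection_stats,
    trim_adapter_read,
    trim_tailed_read,
)
from .profile import (
    EndProfile,
    MappingReport,
    TargetSeq,
    build_profile,
    length_histogram,
    map_read_long,
    map_read_short,
)
from .merge import (
    AmbiguityMap,
    MergeResult,
    Window,
    annotate_ambiguity,
    collapse_distribution,
    merge_two_libraries,
    merged_read_counts,
    position_sd,
)
from .simulate import SimulatedProfile, compare_profiles, simulate_tailed_profile
from .synth import SynthSpec, TailLenDist, generate_library, truth_collapsed_profile

__version__ = "0.1.0"


def example_data_path(name: str):
    """Path to a packaged example data file (FASTA target or count TSV)."""
    path = _resources.files("tailend").joinpath("data", name)
    if not path.is_file():
        raise FileNotFoundError(f"no packaged data file named {name!r}")
    return path


def profile_from_count_table(table: CountTable, label: str, tail_base=None) -> EndProfile:
    """Build an EndProfile directly from a per-position count table."""
    return EndProfile(
        target_id=table.target_id,
        library_label=label,
        counts=table.counts,
        total_mapped=table.total,
        tail_base=tail_base,
    )
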