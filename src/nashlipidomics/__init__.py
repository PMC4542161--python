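"""Hepatic lipidomics profiling for two-group, two-age liver studies.

Raw LC-MS peak tables go in; internal-standard-normalized abundances, lipid
class totals, exact Mann-Whitney group comparisons, within-class composition
panels, fatty-acyl side-chain fractions, and eicosanoid pathway ratios come
out. A seeded synthetic-study generator provides ground-truthed inputs for
testing every stage.
"""

__version__ = "0.1.0"

from .catalogue import (FattyAcyl, LipidCatalogue, LipidSpecies, Linkage,
                        ParseError, class_counts, format_species_name,
                        parse_chain_assignment, parse_species_name,
                        reference_catalogue, validate_catalogue)
from .composition import (acyl_multiplicity, composition_profile,
                          flag_large_changes, percent_change,
                          reference_panel, sidechain_fraction,
                          sidechain_fraction_table,
                          species_percent_within_class)
from .eicosanoids import (PATHWAYS, normalize_areas, pathway_means,
                          pathway_summary, relative_to_arachidonate)
from .normalize import (NormalizationError, StandardMap, match_standard,
                        normalize_table)
from .pipeline import ConfigError, RunConfig, parse_contrast, run_pipeline
from .profile_stats import (Contrast, DEFAULT_CONTRASTS, class_total,
                            class_totals_table, compare_units,
                            fold_change_matrix, mann_whitney_exact,
                            venn_counts)
from .synthetic_data import (EICOSANOID_PRESETS, EffectSpec, PRESETS,
                             StudyDesign, generate_eicosanoid_study,
                             generate_study, write_study)

__all__ = [name for name in dir() if not name.startswith("_")]
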