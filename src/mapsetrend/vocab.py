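"""Closed vocabularies shared by every table in the pipeline."""

WALLS = ("anterior", "inferior", "lateral", "septal")
TIMEPOINTS = ("pre_cpb", "icu")
METHODS = ("auto", "manual")
OBSERVERS = ("obs1", "obs2", "obs3")
RATINGS = ("present", "absent", "indeterminate")

#: The four RWMA patterns: location relative to the monitored wall x temporal behaviour.
PATTERNS = ("remote_dynamic", "remote_persistent", "same_dynamic", "same_persistent")

COHORT_COLUMNS = ("patient_id", "timepoint", "wall", "method", "mapse_mm", "n_cycles")
RATINGS_COLUMNS = ("patient_id", "timepoint", "wall", "observer", "rating")
TRACK_COLUMNS = ("frame_index", "time_s", "long_pos_mm", "detected")
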