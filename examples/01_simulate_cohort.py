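"""Simulate one subject of the 4-category x 4-level cue paradigm.

Builds the default 96-trial schedule (4 blocks of 24, ~1/3 actualized,
12 s trials, 10-12 s jittered ITIs snapped to the 2 s TR), fills
pleasantness ratings with opposing magnitude trends for rewards vs
punishments, and prints the design balance.
"""

from valmux import synth
from valmux.config import StudyConfig

cfg = StudyConfig(seed=7)
trials = synth.generate_ratings(cfg, cfg.subject_seeds()[0])

print(trials.head(8).to_string(index=False))
print()
cells = trials.groupby(["category", "level"]).agg(
    n=("rating", "size"),
    actualized=("actualized", "sum"),
    mean_rating=("rating", "mean"),
)
print(cells.to_string())
print()
print("Each of the 16 conditions appears 6 times, 2 of them actualized;")
print("mean ratings rise with level for gain/face and fall for loss/shock.")
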