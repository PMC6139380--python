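"""Single source of truth for documented default parameter values.

Every module (presets, config loading, CLI flags) reads defaults from
this table so the documentation and the code cannot diverge.
"""

DEFAULTS = {
    "sigma": 0.01,       # per-step Gaussian noise sd (shared by both processes)
    "threshold": 30.0,   # accumulator magnitude at which a trial decides
    "max_steps": 50_000, # trial-length cap; exceeding it is a non-decision
    "init": (0.0, 0.0),  # trials start at the saddle
    "alpha": 0.0,        # fast-toward-slow coupling
    "beta": 0.0,         # slow-toward-fast coupling
}
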