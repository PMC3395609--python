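"""Canonical parameter table for the Aaslid-Tiecks autoregulation model.

Each autoregulation index (ARI) maps to a (T, D, K) triple: T is the time
constant in seconds, D the damping factor, K the autoregulatory gain.
ARI 0 has K = 0 (feedback disabled, flow passively follows pressure);
ARI 9 is the fastest, best-damped regulation.  Values follow the model's
original parameter table (Tiecks, Lam, Aaslid & Newell, Stroke 1995).
Overridable via TiecksParams construction.
"""

# ari: (T [s], D [-], K [-])
ARI_TABLE: dict[int, tuple[float, float, float]] = {
    0: (2.00, 0.00, 0.00),
    1: (2.00, 1.60, 0.20),
    2: (2.00, 1.50, 0.40),
    3: (2.00, 1.15, 0.60),
    4: (2.00, 0.90, 0.80),
    5: (1.90, 0.75, 0.90),
    6: (1.60, 0.65, 0.94),
    7: (1.20, 0.55, 0.96),
    8: (0.87, 0.52, 0.97),
    9: (0.65, 0.50, 0.98),
}

# Default critical closing pressure (mmHg) used to normalise pressure
# deviations; configurable down to 0.
DEFAULT_CRCP = 12.0
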