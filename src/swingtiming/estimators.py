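"""Estimator-style interfaces to the microtiming pipeline.

Two small classes wrap the functional core in the fit/transform idiom so
they compose with scikit-learn tooling (``get_params``/``set_params``,
cloning, pipelines over lists of performances):

* :class:`MicrotimingAnalyzer` — ``fit(performance)`` measures the
  microtiming profile and exposes it as fitted attributes
  (``b_bar_``, ``s_bar_``, ``sigma_b_ms_``, ``r_``, ``rho_b_to_s_`` ...).
* :class:`DeviationScaler` — ``fit(performance)`` learns the grid and the
  deviations, ``transform(performance)`` returns the version with every
  deviation multiplied by ``m`` (``m=0`` quantizes, ``m=2`` exaggerates,
  ``m=-1`` inverts).
"""

from __future__ import annotations

from typing import Optional

from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .manipulate import ManipulationSpec, PRESETS, apply_manipulation
from .microtiming import MTDProfile, analyze_performance
from .midi_io import Performance

__all__ = ["MicrotimingAnalyzer", "DeviationScaler"]


class MicrotimingAnalyzer(BaseEstimator):
    """Measure the microtiming profile of a swung-eighth performance.

    Parameters
    ----------
    sigma_mode : {'bin', 'all'}
        'bin' uses one deviation per temporal bin (earliest note of a
        chord); 'all' lets every note contribute to the spread and swing
        ratio.  Serial correlations always use the bin rule.
    use_anchor_distance : bool
        Measure the one-quarter pairing distance for serial correlations
        between bin anchors (default) rather than raw onsets.

    Attributes (after ``fit``)
    --------------------------
    profile_ : MTDProfile
    b_bar_, s_bar_ : float — mean base/swing positions in ticks.
    sigma_b_ms_, sigma_s_ms_ : float or None — deviation spreads in ms.
    r_, delta_r_ : float — average per-note swing ratio and its SD.
    rho_b_to_s_, rho_s_to_b_ : float or None — Spearman serial correlations.
    middle_fraction_ : float — share of middle-triplet (disregarded) notes.
    """

    def __init__(self, sigma_mode: str = "bin", use_anchor_distance: bool = True):
        self.sigma_mode = sigma_mode
        self.use_anchor_distance = use_anchor_distance

    def fit(self, X: Performance, y=None) -> "MicrotimingAnalyzer":
        if not isinstance(X, Performance):
            raise TypeError(f"expected a Performance, got {type(X).__name__}")
        profile = analyze_performance(
            X, sigma_mode=self.sigma_mode, use_anchor_distance=self.use_anchor_distance
        )
        self.profile_ = profile
        self.b_bar_ = profile.b_bar
        self.s_bar_ = profile.s_bar
        self.sigma_b_ms_ = profile.sigma_b_ms
        self.sigma_s_ms_ = profile.sigma_s_ms
        self.mean_dev_ms_ = profile.mean_dev_ms
        self.r_ = profile.r
        self.delta_r_ = profile.delta_r
        self.rho_b_to_s_ = profile.rho_b_to_s
        self.rho_s_to_b_ = profile.rho_s_to_b
        self.middle_fraction_ = profile.middle_fraction
        self.n_deviations_ = len(profile.deviations)
        return self

    def fit_profile(self, X: Performance) -> MTDProfile:
        """Convenience: fit and return the profile in one call."""
        return self.fit(X).profile_


class DeviationScaler(BaseEstimator):
    """Scale every microtiming deviation of a performance by ``m``.

    The grid (class means) is learned in ``fit`` and reapplied in
    ``transform``; calling ``fit_transform`` on one performance is the
    ordinary single-recording manipulation.  ``preset`` overrides ``m``
    when given ('quantized', 'exaggerated', 'inverted', 'original').
    """

    def __init__(
        self,
        m: float = 1.0,
        preset: Optional[str] = None,
        chord_mode: str = "rigid_bin",
        clamp_negative_onsets: bool = True,
    ):
        self.m = m
        self.preset = preset
        self.chord_mode = chord_mode
        self.clamp_negative_onsets = clamp_negative_onsets

    @property
    def effective_m(self) -> float:
        return PRESETS[self.preset] if self.preset is not None else self.m

    def _spec(self) -> ManipulationSpec:
        return ManipulationSpec(
            m=self.effective_m,
            chord_mode=self.chord_mode,
            clamp_negative_onsets=self.clamp_negative_onsets,
        )

    def fit(self, X: Performance, y=None) -> "DeviationScaler":
        if not isinstance(X, Performance):
            raise TypeError(f"expected a Performance, got {type(X).__name__}")
        analyzer = MicrotimingAnalyzer()
        self.profile_ = analyzer.fit_profile(X)
        self.n_notes_ = len(X.notes)
        return self

    def transform(self, X: Performance) -> Performance:
        check_is_fitted(self, "profile_")
        if len(X.notes) != self.n_notes_:
            raise ValueError("transform input does not match the fitted performance")
        return apply_manipulation(
            X,
            self._spec(),
            means=self.profile_.means,
            deviations=self.profile_.deviations,
        )

    def fit_transform(self, X: Performance, y=None) -> Performance:
        return self.fit(X).transform(X)
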