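"""Spectral preprocessing operators and composable chains.

Implements the standard chemometric pretreatments — Savitzky–Golay
smoothing/derivatives, detrending, multiplicative scatter correction (MSC)
and standard normal variate (SNV) — as pure functions on
:class:`~meatspec.spectra.SpectraSet`, plus an ordered
:class:`PreprocessingChain` that can be fitted on a calibration set and
replayed frozen on prediction spectra (the MSC reference is the only
stateful quantity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectraSet

__all__ = [
    "ChainStep",
    "PreprocessingChain",
    "CHAIN_PRESETS",
    "get_preset",
    "trim_wavelengths",
    "snv",
    "msc",
    "detrend",
    "sg_filter",
    "log_inverse",
    "apply_chain",
]

_STEP_NAMES = {
    "sg_smooth",
    "first_derivative",
    "second_derivative",
    "msc",
    "snv",
    "detrend",
    "log_inverse",
}


# ----------------------------------------------------------------------
# Individual operators


def trim_wavelengths(s: SpectraSet, low: float, high: float) -> SpectraSet:
    """Keep the columns with ``low <= lambda <= high`` (closed interval)."""
    if not low < high:
        raise ValueError("low must be below high")
    keep = (s.wavelengths >= low - 1e-9) & (s.wavelengths <= high + 1e-9)
    if not keep.any():
        raise ValueError(
            f"trim [{low}, {high}] nm retains no wavelengths from grid "
            f"[{s.wavelengths[0]}, {s.wavelengths[-1]}]"
        )
    return s.with_reflectance(s.reflectance[:, keep], wavelengths=s.wavelengths[keep])


def snv(s: SpectraSet) -> SpectraSet:
    """Standard normal variate: per-row standardisation to mean 0, sd 1.

    Uses the sample (n-1) standard deviation.
    """
    x = s.reflectance
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = np.nonzero(sd.ravel() < 1e-15)[0]
    if flat.size:
        raise ValueError(
            f"SNV undefined for constant spectrum of sample {s.sample_ids[flat[0]]!r}"
        )
    return s.with_reflectance((x - mean) / sd)


def msc(s: SpectraSet, reference: np.ndarray | None = None) -> SpectraSet:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum ``x`` is regressed as ``x ~ a + b * reference`` by
    ordinary least squares and corrected to ``(x - a) / b``.  When no
    reference is supplied the column-wise mean spectrum of ``s`` is used;
    the reference actually used is stored in ``result.attrs['msc_reference']``
    so it can be replayed on prediction spectra.
    """
    x = s.reflectance
    if reference is None:
        reference = x.mean(axis=0)
    reference = np.asarray(reference, dtype=float).ravel()
    if reference.size != s.n_wavelengths:
        raise ValueError("MSC reference length does not match the wavelength grid")

    ref_c = reference - reference.mean()
    denom = ref_c @ ref_c
    if denom < 1e-30:
        raise ValueError("MSC reference spectrum is constant")
    b = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    small = np.nonzero(np.abs(b) < 1e-12)[0]
    if small.size:
        raise ValueError(
            f"MSC slope vanishes for sample {s.sample_ids[small[0]]!r} "
            "(spectrum uncorrelated with the reference)"
        )
    a = x.mean(axis=1) - b * reference.mean()
    out = s.with_reflectance((x - a[:, None]) / b[:, None])
    out.attrs["msc_reference"] = reference.copy()
    return out


def detrend(s: SpectraSet, order: int = 2) -> SpectraSet:
    """Subtract a per-row least-squares polynomial baseline in wavelength."""
    if order < 0:
        raise ValueError("order must be >= 0")
    if s.n_wavelengths <= order:
        raise ValueError("grid must have more points than the polynomial order")
    # centred/scaled wavelength axis for conditioning
    w = s.wavelengths
    t = (w - w.mean()) / max(np.ptp(w) / 2.0, 1.0)
    vander = np.vander(t, order + 1, increasing=True)
    q, _ = np.linalg.qr(vander)
    x = s.reflectance
    return s.with_reflectance(x - (x @ q) @ q.T)


def sg_filter(
    s: SpectraSet, window: int = 5, polyorder: int = 2, deriv: int = 0
) -> SpectraSet:
    """Savitzky–Golay filtering (smoothing or derivative) on a uniform grid.

    Derivatives are scaled by the grid step so units are per nm.  Edges use
    the polynomial fitted on the first/last window evaluated at the edge
    points, so polynomials of degree <= ``polyorder`` pass through exactly.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if polyorder >= window:
        raise ValueError("polyorder must be below the window length")
    if deriv > polyorder:
        raise ValueError("derivative order must not exceed polyorder")
    if s.n_wavelengths < window:
        raise ValueError("grid shorter than the filter window")
    steps = np.diff(s.wavelengths)
    step = steps.mean()
    if deriv > 0 and np.any(np.abs(steps - step) > 1e-6 * step):
        raise ValueError("derivatives require a uniform wavelength grid")
    out = savgol_filter(
        s.reflectance, window_length=window, polyorder=polyorder,
        deriv=deriv, delta=step, axis=1, mode="interp",
    )
    return s.with_reflectance(out)


def log_inverse(s: SpectraSet) -> SpectraSet:
    """Apparent absorbance transform ``log10(1 / R)``; requires R > 0."""
    if np.any(s.reflectance <= 0):
        raise ValueError("log(1/R) requires strictly positive reflectance")
    return s.with_reflectance(-np.log10(s.reflectance))


# ----------------------------------------------------------------------
# Chains


@dataclass(frozen=True)
class ChainStep:
    name: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _STEP_NAMES:
            raise ValueError(f"unknown preprocessing step {self.name!r}")


@dataclass
class PreprocessingChain:
    """Ordered, parameterised list of preprocessing steps."""

    steps: list[ChainStep]
    label: str = ""

    def __post_init__(self) -> None:
        names = [st.name for st in self.steps]
        if "msc" in names and "snv" in names:
            raise ValueError("a chain must not contain both MSC and SNV")
        for st in self.steps:
            if st.name in ("sg_smooth", "first_derivative", "second_derivative"):
                window = st.params.get("window", 5)
                polyorder = st.params.get("polyorder", 2)
                if window % 2 == 0 or window < 3 or polyorder >= window:
                    raise ValueError(
                        f"step {st.name!r}: window must be odd >= 3 and "
                        "polyorder < window"
                    )
        if not self.label:
            self.label = " + ".join(names) if names else "original"

    def to_dict(self) -> dict[str, Any]:
        return {
            "label": self.label,
            "steps": [{"name": st.name, "params": dict(st.params)} for st in self.steps],
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PreprocessingChain":
        steps = [ChainStep(st["name"], dict(st.get("params", {}))) for st in d["steps"]]
        return cls(steps=steps, label=d.get("label", ""))


def _sg(window: int = 5, polyorder: int = 2) -> dict[str, Any]:
    return {"window": window, "polyorder": polyorder}


#: The chain variants compared throughout: raw spectra, single scatter
#: corrections, S–G smoothing, S–G derivatives, and the two combined
#: smoothing + detrend + scatter-correction chains.
CHAIN_PRESETS: dict[str, PreprocessingChain] = {
    "original": PreprocessingChain([], label="Original spectra"),
    "msc": PreprocessingChain([ChainStep("msc")], label="MSC"),
    "snv": PreprocessingChain([ChainStep("snv")], label="SNV"),
    "sg": PreprocessingChain(
        [ChainStep("sg_smooth", _sg())], label="S-G smoothing"
    ),
    "sg_1der": PreprocessingChain(
        [ChainStep("first_derivative", _sg())], label="S-G + 1st Der"
    ),
    "sg_2der": PreprocessingChain(
        [ChainStep("second_derivative", _sg())], label="S-G + 2nd Der"
    ),
    "sg_detrend_msc": PreprocessingChain(
        [ChainStep("sg_smooth", _sg()), ChainStep("detrend", {"order": 2}), ChainStep("msc")],
        label="S-G + Detrend + MSC",
    ),
    "sg_detrend_snv": PreprocessingChain(
        [ChainStep("sg_smooth", _sg()), ChainStep("detrend", {"order": 2}), ChainStep("snv")],
        label="S-G + Detrend + SNV",
    ),
}


def get_preset(name: str) -> PreprocessingChain:
    try:
        chain = CHAIN_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown chain preset {name!r}; available: {sorted(CHAIN_PRESETS)}"
        ) from None
    return PreprocessingChain.from_dict(chain.to_dict())


def apply_chain(
    s: SpectraSet,
    chain: PreprocessingChain,
    fitted_state: dict[str, Any] | None = None,
) -> tuple[SpectraSet, dict[str, Any]]:
    """Apply ``chain`` in order; fit stateful steps or replay a frozen state.

    When ``fitted_state`` is None the chain is fitted (the MSC reference is
    the mean spectrum of the data at that stage) and the state returned; a
    returned state replayed on new spectra freezes those references.
    """
    replay = fitted_state is not None
    if replay:
        stored_grid = np.asarray(fitted_state["wavelengths"], dtype=float)
        if stored_grid.size != s.n_wavelengths or not np.allclose(
            stored_grid, s.wavelengths, atol=1e-9
        ):
            raise ValueError("fitted_state grid does not match the input spectra grid")
        step_states = fitted_state["steps"]
        if len(step_states) != len(chain.steps):
            raise ValueError("fitted_state does not match the chain length")
    else:
        step_states = [None] * len(chain.steps)

    out = s
    for i, st in enumerate(chain.steps):
        if st.name == "sg_smooth":
            out = sg_filter(out, deriv=0, **st.params)
        elif st.name == "first_derivative":
            out = sg_filter(out, deriv=1, **st.params)
        elif st.name == "second_derivative":
            out = sg_filter(out, deriv=2, **st.params)
        elif st.name == "detrend":
            out = detrend(out, **st.params)
        elif st.name == "snv":
            out = snv(out)
        elif st.name == "log_inverse":
            out = log_inverse(out)
        elif st.name == "msc":
            reference = None
            if replay:
                reference = np.asarray(step_states[i]["reference"], dtype=float)
            out = msc(out, reference=reference)
            if not replay:
                step_states[i] = {"reference": out.attrs["msc_reference"].tolist()}
        else:  # pragma: no cover - guarded by ChainStep validation
            raise ValueError(f"unknown step {st.name!r}")

    state = {"wavelengths": s.wavelengths.tolist(), "steps": step_states}
    return out, state
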