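"""The per-sample measurement container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ArrayProfile"]


@dataclass
class ArrayProfile:
    """One array's log2(test/reference) value per probe of a ProbeMap.

    Attributes
    ----------
    sample_id, line_id
        Identity of the hybridized animal and the line/breed it belongs to.
        Self-self control arrays carry line_id ``"self_self"``.
    values
        log2 ratios, one per probe, in probe-map order.
    covariate
        Optional per-probe nuisance covariate (a mean-signal proxy) against
        which dye-bias trends are fitted during normalization.
    sex
        ``"F"`` or ``"M"``; relevant only for Z/W dosage in simulations and
        for optional per-sex-chromosome centering.
    """

    sample_id: str
    line_id: str
    values: np.ndarray
    covariate: np.ndarray | None = None
    sex: str = "F"
    normalized: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.covariate is not None:
            self.covariate = np.asarray(self.covariate, dtype=float)
            if self.covariate.shape != self.values.shape:
                raise ValueError("covariate length must match values length")

    def __len__(self) -> int:
        return len(self.values)

    def copy_with(self, values: np.ndarray, normalized: bool | None = None) -> "ArrayProfile":
        return ArrayProfile(
            sample_id=self.sample_id,
            line_id=self.line_id,
            values=np.asarray(values, dtype=float),
            covariate=None if self.covariate is None else self.covariate.copy(),
            sex=self.sex,
            normalized=self.normalized if normalized is None else normalized,
        )
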