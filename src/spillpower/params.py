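"""Structural parameters of the spillover data-generating process.

The causal chain is

    Treatment --phi1--> U1 --beta_u1--> PEB1 --phi22--> U2 --beta_u2--> PEB2
                          \\----------phi21------------/
    Nudge (IV) --beta_iv--> PEB1

where U1 and U2 are latent "activation systems" (Gaussian), PEB1/PEB2 are the
two pro-environmental behaviors, and the salience nudge acts as an
instrumental variable on PEB1 only.  Two observation models are supported:
``binary`` (behaviors are Bernoulli draws through a logit link) and
``continuous`` (behaviors are Gaussian with the same linear means).
"""

from __future__ import annotations

import dataclasses
import enum
import json
import pathlib
from typing import Any, Mapping

import yaml

__all__ = ["DGPVersion", "GenerativeParams", "InvalidParameterError"]


class InvalidParameterError(ValueError):
    """Raised when structural parameters violate their domain constraints."""


class DGPVersion(str, enum.Enum):
    """Observation model of the data-generating process."""

    BINARY = "binary"
    CONTINUOUS = "continuous"


@dataclasses.dataclass(frozen=True)
class GenerativeParams:
    """All structural coefficients of the spillover causal model.

    Parameters
    ----------
    version:
        ``binary`` (logit/Bernoulli outcomes) or ``continuous`` (Gaussian).
    phi1:
        Effect of the treatment on the first activation system U1.
    phi21:
        Autocorrelation path U1 -> U2.
    phi22:
        Effect of the realized first behavior on U2.
    beta_u1, beta_u2:
        Loadings of U1 on PEB1 and of U2 on PEB2 ("entry" and "exit" signal).
    beta_iv:
        Effect of the salience nudge (the instrument) on PEB1.
    attract_peb1, attract_peb2:
        Intrinsic attractiveness intercepts (logit scale in the binary
        version, outcome scale in the continuous version).
    sigma_u1, sigma_u2:
        Standard deviations of the activation-system noise; strictly positive.
    sigma_peb1, sigma_peb2:
        Outcome noise SDs; used by the continuous version only and ignored
        (but still validated) in the binary version.
    """

    version: DGPVersion
    phi1: float
    phi21: float
    phi22: float
    beta_u1: float
    beta_u2: float
    beta_iv: float
    attract_peb1: float
    attract_peb2: float
    sigma_u1: float = 1.0
    sigma_u2: float = 1.0
    sigma_peb1: float = 1.0
    sigma_peb2: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "version", DGPVersion(self.version))
        for name in ("sigma_u1", "sigma_u2", "sigma_peb1", "sigma_peb2"):
            value = getattr(self, name)
            if not value > 0:
                raise InvalidParameterError(
                    f"{name} must be strictly positive, got {value!r}"
                )

    @property
    def unused_fields(self) -> tuple[str, ...]:
        """Fields that the current observation model ignores."""
        if self.version is DGPVersion.BINARY:
            return ("sigma_peb1", "sigma_peb2")
        return ()

    def replace(self, **changes: Any) -> "GenerativeParams":
        return dataclasses.replace(self, **changes)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["version"] = self.version.value
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "GenerativeParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(
                f"unknown parameter keys: {sorted(unknown)}"
            )
        missing = {
            f.name
            for f in dataclasses.fields(cls)
            if f.default is dataclasses.MISSING
        } - set(data)
        if missing:
            raise InvalidParameterError(f"missing parameter keys: {sorted(missing)}")
        return cls(**dict(data))

    def to_file(self, path: str | pathlib.Path) -> None:
        path = pathlib.Path(path)
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | pathlib.Path) -> "GenerativeParams":
        path = pathlib.Path(path)
        text = path.read_text()
        data = (
            yaml.safe_load(text)
            if path.suffix in (".yml", ".yaml")
            else json.loads(text)
        )
        return cls.from_dict(data)
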