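"""Flow-cytometric genome-size estimation.

The 2C DNA content of a sample is the reference 2C content scaled by the
ratio of the two fluorescence peak positions:

    sample 2C [pg] = reference 2C [pg] * (sample peak / reference peak)

and the haploid genome size in gigabases follows from the DNA mass-to-
length constant 0.978 Gb per pg:

    haploid size [Gb] = 0.978 * 2C / 2

Rounding happens only at the reporting layer (one decimal for pg, two for
Gb); intermediate values keep full precision, which matters because the
printed haploid size is only reproducible from the unrounded 2C value.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InputError

PG_TO_GB = 0.978  # gigabases per picogram of DNA

VICIA_FABA_2C_PG = 26.9  # standard broad-bean reference nuclei


@dataclass(frozen=True)
class CytometryMeasurement:
    ref_2c_pg: float
    ref_peak: float
    sample_peak: float

    def validate(self) -> None:
        if min(self.ref_2c_pg, self.ref_peak, self.sample_peak) <= 0:
            raise InputError("all cytometry quantities must be positive")


def estimate_2c(m: CytometryMeasurement) -> float:
    """Sample 2C DNA content in picograms (unrounded)."""
    m.validate()
    return m.ref_2c_pg * m.sample_peak / m.ref_peak


def haploid_size_gb(two_c_pg: float) -> float:
    """Haploid genome size in gigabases from a 2C value in picograms."""
    if two_c_pg <= 0:
        raise InputError("2C value must be positive")
    return PG_TO_GB * two_c_pg / 2.0


def genome_size_report(m: CytometryMeasurement) -> dict[str, float]:
    """Full-precision estimates plus values rounded as conventionally printed."""
    two_c = estimate_2c(m)
    gb = haploid_size_gb(two_c)
    return {
        "two_c_pg": two_c,
        "haploid_gb": gb,
        "two_c_pg_printed": round(two_c, 1),
        "haploid_gb_printed": round(gb, 2),
    }
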