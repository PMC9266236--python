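"""Packaged demonstration study: two synthetic cities, ten summers.

One canonical synthetic configuration used by the worked example, the
end-to-end tests and the acceptance script.  The scenario represents a
sunny low-latitude summer whose working-hour WBGT* distribution spans
all four flag categories (so threshold behaviour is exercised), with a
+1.0 degC additive warming between the 2010-2014 and 2015-2019 periods.
"""

from __future__ import annotations

from .pipeline import PipelineConfig
from .synthetic import ClimateScenario

__all__ = ["demo_scenario", "demo_cities", "demo_config"]

#: additive warming (degC) of the later period in the demo scenario
DEMO_WARMING = 1.0


def demo_scenario(seed: int = 7) -> ClimateScenario:
    """The demo climate: 6x6 degree grid around 25 N, moderate humidity,
    strong clear-sky sun, diurnal range 10 degC, 0.5 degC noise."""
    return ClimateScenario(
        grid_extent=(22.0, 28.0, 70.0, 76.0),
        base_temperature=20.0,
        diurnal_amplitude=5.0,
        dewpoint_depression_mean=10.0,
        wind_mean=2.0,
        clear_sky_peak_flux=850.0,
        period_offsets={"2010-2014": 0.0, "2015-2019": DEMO_WARMING},
        noise_sd=0.5,
        seed=seed,
    )


def demo_cities() -> list[dict]:
    """Two synthetic 4x4-window cities inside the demo grid."""
    return [
        {"name": "DemoA", "country": "synthetic", "lat": 24.0, "lon": 72.0,
         "region_class": "europe", "population": 1000},
        {"name": "DemoB", "country": "synthetic", "lat": 26.0, "lon": 74.0,
         "region_class": "europe", "population": 2000},
    ]


def demo_config(output_dir, seed: int = 7) -> PipelineConfig:
    """Full pipeline config for the demo study (2 cities x 10 seasons)."""
    return PipelineConfig(
        scenario=demo_scenario(seed),
        cities=demo_cities(),
        periods=("2015-2019", "2010-2014"),
        land_fraction_target=1.0,
        output_dir=output_dir,
        seed=seed,
    )
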