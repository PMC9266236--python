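# Metropolitan areas analysed by the pipeline.
#
# region_class: asia_na -> 8x8 grid-cell window (~200 km at 0.25 deg);
#               europe  -> 4x4 window (~100 km).
# Cairo is assigned the asia_na class (no class is standard for Africa;
# see docs/methods.md).
# Populations in thousands (Demographia World Urban Areas, 2019).
# Center coordinates are well-known city centers chosen for this package;
# they are not part of any published table.
- {name: Tokyo,       country: Japan,        lat: 35.68,  lon: 139.69,  region_class: asia_na, population: 37977}
- {name: Delhi,       country: India,        lat: 28.61,  lon: 77.21,   region_class: asia_na, population: 29617}
- {name: Seoul,       country: South Korea,  lat: 37.57,  lon: 126.98,  region_class: asia_na, population: 21794}
- {name: Bangkok,     country: Thailand,     lat: 13.76,  lon: 100.50,  region_class: asia_na, population: 17066}
- {name: Dhaka,       country: Bangladesh,   lat: 23.81,  lon: 90.41,   region_class: asia_na, population: 15443}
- {name: Karachi,     country: Pakistan,     lat: 24.86,  lon: 67.01,   region_class: asia_na, population: 15400}
- {name: Kathmandu,   country: Nepal,        lat: 27.72,  lon: 85.32,   region_class: asia_na, population: 3045}
- {name: Shanghai,    country: China,        lat: 31.23,  lon: 121.47,  region_class: asia_na, population: 22120}
- {name: Guangzhou,   country: China,        lat: 23.13,  lon: 113.26,  region_class: asia_na, population: 20902}
- {name: Beijing,     country: China,        lat: 39.90,  lon: 116.41,  region_class: asia_na, population: 19433}
- {name: Paris,       country: France,       lat: 48.86,  lon: 2.35,    region_class: europe,  population: 11020}
- {name: Madrid,      country: Spain,        lat: 40.42,  lon: -3.70,   region_class: europe,  population: 6026}
- {name: Roma,        country: Italy,        lat: 41.89,  lon: 12.48,   region_class: europe,  population: 3995}
- {name: Marseille,   country: France,       lat: 43.30,  lon: 5.37,    region_class: europe,  population: 1605}
- {name: Zurich,      country: Switzerland,  lat: 47.38,  lon: 8.54,    region_class: europe,  population: 805}
- {name: Cairo,       country: Egypt,        lat: 30.04,  lon: 31.24,   region_class: asia_na, population: 10025}
- {name: Mexico City, country: Mexico,       lat: 19.43,  lon: -99.13,  region_class: asia_na, population: 20996}
- {name: New York,    country: USA,          lat: 40.71,  lon: -74.01,  region_class: asia_na, population: 20870}
- {name: Los Angeles, country: USA,          lat: 34.05,  lon: -118.24, region_class: asia_na, population: 15402}
- {name: Houston,     country: USA,          lat: 29.76,  lon: -95.37,  region_class: asia_na, population: 6406}
- {name: Minneapolis, country: USA,          lat: 44.98,  lon: -93.27,  region_class: asia_na, population: 2855}
- {name: Denver,      country: USA,          lat: 39.74,  lon: -104.99, region_class: asia_na, population: 2690}
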