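{
  "name": "sentinel2-bonafoni-sekertekin-2020",
  "provenance": "Narrow-to-broadband shortwave albedo conversion coefficients for Sentinel-2 surface reflectance, transcribed from Bonafoni & Sekertekin (2020), IEEE Geoscience and Remote Sensing Letters 17(9), 1618-1622, doi:10.1109/LGRS.2020.2967085.",
  "offset": 0.0,
  "weights": {
    "B2": 0.2266,
    "B3": 0.1236,
    "B4": 0.1573,
    "B8": 0.3417,
    "B11": 0.1170,
    "B12": 0.0338
  }
}
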