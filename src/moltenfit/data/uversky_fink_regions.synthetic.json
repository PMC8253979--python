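{
  "provenance": "SYNTHETIC approximate region boundaries for the double-wavelength ([theta]200, [theta]222) conformational plot. The canonical plot groups proteins into ordered/molten-globule, pre-molten-globule and coil-like clusters; the published figure does not print polygon coordinates, so these rectangles were transcribed approximately from the cluster centroids and spreads commonly quoted for it (coil-like: [theta]200 ~ -18500 +/- 2500, [theta]222 ~ -1700 +/- 700; pre-molten globule: [theta]200 ~ -10700 +/- 1300, [theta]222 ~ -3900 +/- 1100; molten globule: substantially negative [theta]222 with moderate [theta]200). Units deg cm^2 dmol^-1. Replace this file with measured boundaries for quantitative work.",
  "regions": {
    "coil_like": [
      [-21000.0, -2400.0],
      [-16000.0, -2400.0],
      [-16000.0, -1000.0],
      [-21000.0, -1000.0]
    ],
    "pre_molten_globule": [
      [-12000.0, -5000.0],
      [-9400.0, -5000.0],
      [-9400.0, -2800.0],
      [-12000.0, -2800.0]
    ],
    "molten_globule": [
      [-8000.0, -13000.0],
      [-2000.0, -13000.0],
      [-2000.0, -6000.0],
      [-8000.0, -6000.0]
    ]
  }
}
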