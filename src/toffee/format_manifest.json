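{
  "root_attributes": [
    "CREATED_BY_LIBRARY_VERSION",
    "FILE_FORMAT_MAJOR_VERSION",
    "FILE_FORMAT_MINOR_VERSION",
    "IMSType",
    "metadataXML"
  ],
  "group_attributes": [
    "IMSAlpha",
    "IMSBeta",
    "IMSGamma",
    "firstScanRetentionTimeOffset",
    "scanCycleTime",
    "precursorLower",
    "precursorCenter",
    "precursorUpper"
  ],
  "group_datasets": {
    "IMSAlphaPerScan": "float64",
    "IMSBetaPerScan": "float64",
    "retentionTimeIdx": "uint32",
    "imsCoord": "uint32",
    "intensity": "uint32"
  },
  "ms1_group": "ms1",
  "ms2_group_pattern": "ms2-[0-9][0-9][0-9]"
}
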