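"""Published benchmark regression metrics for six spectral models on three
pear quality indices (calibration R2/RMSE, prediction R2/RMSE, RPD).

Used purely as a formula-consistency fixture: the RPD = 1/sqrt(1 - R2)
identity and the constancy of RPD x RMSEP within an index validate the
package's metric conventions against independently printed numbers.
"""

# index -> model -> (Rc2, RMSEC, Rp2, RMSEP, RPD)
BENCHMARK_TABLE = {
    "FI": {
        "SVR": (0.7740, 1.0678, 0.7853, 1.2777, 2.1581),
        "PLSR": (0.7768, 1.0612, 0.8355, 1.1183, 2.4658),
        "PCR": (0.8220, 0.9477, 0.8612, 1.0275, 2.6837),
        "MSCNN": (0.8869, 0.7553, 0.8506, 1.0657, 2.5873),
        "ResNet18": (0.9922, 0.1987, 0.8712, 0.9895, 2.7867),
        "MSCNN-LSTM": (0.9215, 0.6296, 0.8934, 0.9001, 3.0634),
    },
    "SSC": {
        "SVR": (0.8009, 0.8743, 0.7189, 1.1853, 1.8893),
        "PLSR": (0.7279, 1.0221, 0.7275, 1.1689, 1.9158),
        "PCR": (0.7759, 0.9274, 0.7860, 1.0359, 2.1616),
        "MSCNN": (0.8815, 0.6744, 0.8581, 0.8437, 2.6542),
        "ResNet18": (0.9949, 0.1400, 0.8591, 0.8404, 2.6645),
        "MSCNN-LSTM": (0.8690, 0.7092, 0.8731, 0.7976, 2.8076),
    },
    "FSR": {
        "SVR": (0.9003, 0.1073, 0.8378, 0.1810, 2.4829),
        "PLSR": (0.8254, 0.1419, 0.7949, 0.2035, 2.2082),
        "PCR": (0.8495, 0.1318, 0.8317, 0.1844, 2.4374),
        "MSCNN": (0.8996, 0.1076, 0.8357, 0.1822, 2.4671),
        "ResNet18": (0.9859, 0.0403, 0.8539, 0.1718, 2.6159),
        "MSCNN-LSTM": (0.9574, 0.0701, 0.8610, 0.1676, 2.6825),
    },
}

# per-stage reference means used in the worked percent-change examples
STAGE_MEANS = {
    "FI": {"P1": 13.98, "P2": 11.42, "P3": 10.09, "P4": 8.43, "P5": 8.03},
    "SSC": {"P1": 9.13, "P2": 12.87, "P3": 14.55, "P4": 13.22, "P5": 12.51},
    "FSR": {"P1": 1.55, "P2": 0.89, "P3": 0.70, "P4": 0.64, "P5": 0.65},
}
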