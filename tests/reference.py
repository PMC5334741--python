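"""Reference results for the grass-carp case study.

Optimal objective values, solution tables and priority vectors reported for
the case study (printed at 4 decimals), used by the acceptance tests.
"""

# regime I: optimal objectives per principle ("min" row)
TABLE1_MIN = {"freedom": 0.2010, "fraternity": 0.096, "equality": 0.0, "mixed": 0.0481}

# regime I: reported selection coefficients alpha[(i, j, expert)] per principle
TABLE1_ALPHAS = {
    "freedom": {
        (1, 2, 1): 0.4792, (1, 3, 1): 1.0, (1, 4, 1): 0.1, (2, 3, 1): 0.1559,
        (2, 4, 1): 0.2279, (3, 4, 1): 0.1,
        (1, 2, 2): 0.9792, (1, 3, 2): 0.1, (1, 4, 2): 0.1, (2, 3, 2): 0.2890,
        (2, 4, 2): 0.7279, (3, 4, 2): 0.65,
        (1, 2, 3): 0.1, (1, 3, 3): 1.0, (1, 4, 3): 1.0, (2, 3, 3): 0.1,
        (2, 4, 3): 0.8186, (3, 4, 3): 0.1,
    },
    "fraternity": {
        (1, 2, 1): 0.5262, (1, 3, 1): 0.6243, (1, 4, 1): 0.2549, (2, 3, 1): 0.4842,
        (2, 4, 1): 0.3931, (3, 4, 1): 0.4034,
        (1, 2, 2): 0.9361, (1, 3, 2): 0.1123, (1, 4, 2): 0.1112, (2, 3, 2): 0.2815,
        (2, 4, 2): 0.7058, (3, 4, 2): 0.6404,
        (1, 2, 3): 0.1, (1, 3, 3): 0.9982, (1, 4, 3): 1.0, (2, 3, 3): 0.1,
        (2, 4, 3): 0.8030, (3, 4, 3): 0.1,
    },
    "equality": {
        (1, 2, 1): 0.5917, (1, 3, 1): 0.5697, (1, 4, 1): 0.4276, (2, 3, 1): 0.5285,
        (2, 4, 1): 0.4644, (3, 4, 1): 0.5105,
        (1, 2, 2): 0.6361, (1, 3, 2): 0.5288, (1, 4, 2): 0.4961, (2, 3, 2): 0.4384,
        (2, 4, 2): 0.5026, (3, 4, 2): 0.5273,
        (1, 2, 3): 0.5573, (1, 3, 3): 0.6737, (1, 4, 3): 0.6842, (2, 3, 3): 0.4649,
        (2, 4, 3): 0.5197, (3, 4, 3): 0.4081,
    },
}

# regime I: reported upper-triangle ideal entries per principle
TABLE1_IDEALS = {
    "freedom": {(1, 2): 0.2958, (1, 3): 0.4114, (1, 4): 0.5414,
                (2, 3): 0.6156, (2, 4): 0.7456, (3, 4): 0.63},
    "fraternity": {(1, 2): 0.2865, (1, 3): 0.3995, (1, 4): 0.5274,
                   (2, 3): 0.6130, (2, 4): 0.7409, (3, 4): 0.6279},
    "equality": {(1, 2): 0.3406, (1, 3): 0.4203, (1, 4): 0.5204,
                 (2, 3): 0.5796, (2, 4): 0.6797, (3, 4): 0.6001},
}

# full reported freedom-principle crisp ideal (regime I)
FREEDOM_IDEAL_I = [
    [0.5, 0.2958, 0.4114, 0.5414],
    [0.7042, 0.5, 0.6156, 0.7456],
    [0.5886, 0.3844, 0.5, 0.63],
    [0.4586, 0.2544, 0.37, 0.5],
]

# priorities derived from the freedom-principle ideal (regime I)
FREEDOM_PRIORITIES_I = (0.1768, 0.4188, 0.2573, 0.1471)

# regime II: optimal objectives and priority vectors per principle
TABLE2_MIN = {"freedom": 0.2369, "fraternity": 0.12, "equality": 0.0, "mixed": 0.1137}
TABLE2_PRIORITIES = {
    "freedom": (0.1714, 0.4, 0.2571, 0.1714),
    "fraternity": (0.2001, 0.3997, 0.2001, 0.2001),
    "equality": (0.2339, 0.2891, 0.2547, 0.2222),
    "mixed": (0.2025, 0.3347, 0.2603, 0.2025),
}
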