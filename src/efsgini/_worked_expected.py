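"""Frozen expected intermediates for the worked example.

Computed once with independent oracle code: rank correlation and one-way
ANOVA from scipy, plug-in mutual information from a contingency table,
exhaustive split enumeration for the CART tree, and a direct transcription
of the combinator semantics.
"""


EXPECTED = {'cart_on_D': {'feature_ids': ['g4', 'g5', 'g6', 'g7'],
               'importances': {'g4': 0.2222222222,
                               'g5': 0.0,
                               'g6': 0.7777777778,
                               'g7': 0.0},
               'preorder': [('g6', -0.055),
                            ('g6', -1.195),
                            ('g4', 0.19),
                            ('leaf', None),
                            ('leaf', None),
                            ('leaf', None),
                            ('leaf', None)]},
 'f_stat': {'g1': 378.0,
            'g2': 378.0,
            'g3': 3.4486873508,
            'g4': 0.422422499,
            'g5': 0.0036740359,
            'g6': 2.2154850954,
            'g7': 0.8087864663,
            'g8': 3.5627226702},
 'gini_select': {'S1': ['g1', 'g3', 'g4'],
                 'S2': ['g1', 'g3', 'g5'],
                 'S3': ['g1', 'g3', 'g6'],
                 'S4': ['g1', 'g3', 'g7'],
                 'candidate_pool': ['g4', 'g5', 'g6', 'g7'],
                 'final': ['g1', 'g3', 'g6'],
                 'intersection': ['g1', 'g3'],
                 'k': 3},
 'mi_bits': {'g1': 1.0,
             'g2': 1.0,
             'g3': 0.6666666667,
             'g4': 0.5,
             'g5': 0.6666666667,
             'g6': 0.6666666667,
             'g7': 0.8333333333,
             'g8': 1.0},
 'spearman': {'ids': ['g1', 'g2', 'g3', 'g4', 'g5', 'g6', 'g7', 'g8'],
              'matrix': [[1.0,
                          1.0,
                          0.1468531469,
                          0.4825174825,
                          -0.048951049,
                          0.1818181818,
                          -0.0909090909,
                          0.6573426573],
                         [1.0,
                          1.0,
                          0.1468531469,
                          0.4825174825,
                          -0.048951049,
                          0.1818181818,
                          -0.0909090909,
                          0.6573426573],
                         [0.1468531469,
                          0.1468531469,
                          1.0,
                          0.034965035,
                          -0.1678321678,
                          0.3846153846,
                          -0.2027972028,
                          0.0559440559],
                         [0.4825174825,
                          0.4825174825,
                          0.034965035,
                          1.0,
                          0.2167832168,
                          0.2307692308,
                          0.2867132867,
                          0.4125874126],
                         [-0.048951049,
                          -0.048951049,
                          -0.1678321678,
                          0.2167832168,
                          1.0,
                          0.0559440559,
                          -0.3146853147,
                          0.2377622378],
                         [0.1818181818,
                          0.1818181818,
                          0.3846153846,
                          0.2307692308,
                          0.0559440559,
                          1.0,
                          -0.5664335664,
                          -0.1118881119],
                         [-0.0909090909,
                          -0.0909090909,
                          -0.2027972028,
                          0.2867132867,
                          -0.3146853147,
                          -0.5664335664,
                          1.0,
                          -0.041958042],
                         [0.6573426573,
                          0.6573426573,
                          0.0559440559,
                          0.4125874126,
                          0.2377622378,
                          -0.1118881119,
                          -0.041958042,
                          1.0]]}}
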