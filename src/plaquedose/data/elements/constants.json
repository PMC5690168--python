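{
 "note": "generated by scripts/generate_xs_tables.py",
 "r_e_cm": 2.8179403262e-13,
 "hc_keV_A": 12.39841984,
 "mec2_keV": 510.99895,
 "elements": {
  "H": {
   "Z": 1,
   "A": 1.0079,
   "edges": []
  },
  "C": {
   "Z": 6,
   "A": 12.0107,
   "edges": []
  },
  "N": {
   "Z": 7,
   "A": 14.0067,
   "edges": []
  },
  "O": {
   "Z": 8,
   "A": 15.9994,
   "edges": []
  },
  "Na": {
   "Z": 11,
   "A": 22.9898,
   "edges": [
    {
     "shell": "K",
     "E_keV": 1.0721,
     "fluor_yield": 0.023,
     "share_above_edge": 0.91126,
     "higher_edges": [],
     "higher_shares": [],
     "lines": [
      {
       "E_keV": 1.041,
       "frac": 1.0
      }
     ]
    }
   ]
  },
  "Mg": {
   "Z": 12,
   "A": 24.305,
   "edges": [
    {
     "shell": "K",
     "E_keV": 1.305,
     "fluor_yield": 0.03,
     "share_above_edge": 0.92237,
     "higher_edges": [],
     "higher_shares": [],
     "lines": [
      {
       "E_keV": 1.254,
       "frac": 1.0
      }
     ]
    }
   ]
  },
  "Si": {
   "Z": 14,
   "A": 28.0855,
   "edges": [
    {
     "shell": "K",
     "E_keV": 1.8389,
     "fluor_yield": 0.05,
     "share_above_edge": 0.91412,
     "higher_edges": [],
     "higher_shares": [],
     "lines": [
      {
       "E_keV": 1.74,
       "frac": 1.0
      }
     ]
    }
   ]
  },
  "P": {
   "Z": 15,
   "A": 30.9738,
   "edges": [
    {
     "shell": "K",
     "E_keV": 2.1455,
     "fluor_yield": 0.063,
     "share_above_edge": 0.91034,
     "higher_edges": [],
     "higher_shares": [],
     "lines": [
      {
       "E_keV": 2.014,
       "frac": 1.0
      }
     ]
    }
   ]
  },
  "S": {
   "Z": 16,
   "A": 32.065,
   "edges": [
    {
     "shell": "K",
     "E_keV": 2.472,
     "fluor_yield": 0.078,
     "share_above_edge": 0.90665,
     "higher_edges": [],
     "higher_shares": [],
     "lines": [
      {
       "E_keV": 2.308,
       "frac": 1.0
      }
     ]
    }
   ]
  },
  "Cl": {
   "Z": 17,
   "A": 35.453,
   "edges": [
    {
     "shell": "K",
     "E_keV": 2.8224,
     "fluor_yield": 0.097,
     "share_above_edge": 0.90311,
     "higher_edges": [],
     "higher_shares": [],
     "lines": [
      {
       "E_keV": 2.622,
       "frac": 1.0
      }
     ]
    }
   ]
  },
  "Ar": {
   "Z": 18,
   "A": 39.948,
   "edges": [
    {
     "shell": "K",
     "E_keV": 3.2029,
     "fluor_yield": 0.118,
     "share_above_edge": 0.89977,
     "higher_edges": [],
     "higher_shares": [],
     "lines": [
      {
       "E_keV": 2.957,
       "frac": 1.0
      }
     ]
    }
   ]
  },
  "K": {
   "Z": 19,
   "A": 39.0983,
   "edges": [
    {
     "shell": "K",
     "E_keV": 3.6074,
     "fluor_yield": 0.14,
     "share_above_edge": 0.89692,
     "higher_edges": [],
     "higher_shares": [],
     "lines": [
      {
       "E_keV": 3.313,
       "frac": 1.0
      }
     ]
    }
   ]
  },
  "Ca": {
   "Z": 20,
   "A": 40.078,
   "edges": [
    {
     "shell": "K",
     "E_keV": 4.0381,
     "fluor_yield": 0.163,
     "share_above_edge": 0.89446,
     "higher_edges": [],
     "higher_shares": [],
     "lines": [
      {
       "E_keV": 3.691,
       "frac": 0.89
      },
      {
       "E_keV": 4.013,
       "frac": 0.11
      }
     ]
    }
   ]
  },
  "Ti": {
   "Z": 22,
   "A": 47.867,
   "edges": [
    {
     "shell": "K",
     "E_keV": 4.9664,
     "fluor_yield": 0.214,
     "share_above_edge": 0.88929,
     "higher_edges": [],
     "higher_shares": [],
     "lines": [
      {
       "E_keV": 4.509,
       "frac": 0.88
      },
      {
       "E_keV": 4.932,
       "frac": 0.12
      }
     ]
    }
   ]
  },
  "Cu": {
   "Z": 29,
   "A": 63.546,
   "edges": [
    {
     "shell": "K",
     "E_keV": 8.9789,
     "fluor_yield": 0.44,
     "share_above_edge": 0.87603,
     "higher_edges": [],
     "higher_shares": [],
     "lines": [
      {
       "E_keV": 8.041,
       "frac": 0.88
      },
      {
       "E_keV": 8.905,
       "frac": 0.12
      }
     ]
    }
   ]
  },
  "Pd": {
   "Z": 46,
   "A": 106.42,
   "edges": [
    {
     "shell": "K",
     "E_keV": 24.3503,
     "fluor_yield": 0.82,
     "share_above_edge": 0.84818,
     "higher_edges": [],
     "higher_shares": [],
     "lines": [
      {
       "E_keV": 21.124,
       "frac": 0.845
      },
      {
       "E_keV": 23.82,
       "frac": 0.155
      }
     ]
    },
    {
     "shell": "L",
     "E_keV": 3.6043,
     "fluor_yield": 0.049,
     "share_above_edge": 0.74181,
     "higher_edges": [
      24.3503
     ],
     "higher_shares": [
      0.84818
     ],
     "lines": [
      {
       "E_keV": 2.84,
       "frac": 1.0
      }
     ]
    }
   ]
  },
  "Ag": {
   "Z": 47,
   "A": 107.8682,
   "edges": [
    {
     "shell": "K",
     "E_keV": 25.514,
     "fluor_yield": 0.831,
     "share_above_edge": 0.8467,
     "higher_edges": [],
     "higher_shares": [],
     "lines": [
      {
       "E_keV": 22.103,
       "frac": 0.84
      },
      {
       "E_keV": 24.94,
       "frac": 0.16
      }
     ]
    },
    {
     "shell": "L",
     "E_keV": 3.8058,
     "fluor_yield": 0.056,
     "share_above_edge": 0.73895,
     "higher_edges": [
      25.514
     ],
     "higher_shares": [
      0.8467
     ],
     "lines": [
      {
       "E_keV": 2.98,
       "frac": 1.0
      }
     ]
    }
   ]
  },
  "Pt": {
   "Z": 78,
   "A": 195.084,
   "edges": [
    {
     "shell": "L1",
     "E_keV": 13.8799,
     "fluor_yield": 0.318,
     "share_above_edge": 0.13426,
     "higher_edges": [],
     "higher_shares": [],
     "lines": [
      {
       "E_keV": 10.45,
       "frac": 1.0
      }
     ]
    },
    {
     "shell": "L2",
     "E_keV": 13.2726,
     "fluor_yield": 0.356,
     "share_above_edge": 0.28322,
     "higher_edges": [
      13.8799
     ],
     "higher_shares": [
      0.13426
     ],
     "lines": [
      {
       "E_keV": 11.1,
       "frac": 1.0
      }
     ]
    },
    {
     "shell": "L3",
     "E_keV": 11.5637,
     "fluor_yield": 0.306,
     "share_above_edge": 0.61988,
     "higher_edges": [
      13.8799,
      13.2726
     ],
     "higher_shares": [
      0.13426,
      0.28322
     ],
     "lines": [
      {
       "E_keV": 9.442,
       "frac": 0.82
      },
      {
       "E_keV": 11.25,
       "frac": 0.18
      }
     ]
    }
   ]
  },
  "Au": {
   "Z": 79,
   "A": 196.967,
   "edges": [
    {
     "shell": "L1",
     "E_keV": 14.3528,
     "fluor_yield": 0.329,
     "share_above_edge": 0.1342,
     "higher_edges": [],
     "higher_shares": [],
     "lines": [
      {
       "E_keV": 10.86,
       "frac": 1.0
      }
     ]
    },
    {
     "shell": "L2",
     "E_keV": 13.7336,
     "fluor_yield": 0.373,
     "share_above_edge": 0.2841,
     "higher_edges": [
      14.3528
     ],
     "higher_shares": [
      0.1342
     ],
     "lines": [
      {
       "E_keV": 11.44,
       "frac": 1.0
      }
     ]
    },
    {
     "shell": "L3",
     "E_keV": 11.9187,
     "fluor_yield": 0.32,
     "share_above_edge": 0.61831,
     "higher_edges": [
      14.3528,
      13.7336
     ],
     "higher_shares": [
      0.1342,
      0.2841
     ],
     "lines": [
      {
       "E_keV": 9.713,
       "frac": 0.81
      },
      {
       "E_keV": 11.583,
       "frac": 0.19
      }
     ]
    }
   ]
  }
 }
}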