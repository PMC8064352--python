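{
 "format": "branchfold-energy-tables",
 "version": 1,
 "units": "kcal/mol",
 "stack": {
  "AU/AU": "-9/10",
  "AU/CG": "-11/5",
  "AU/GC": "-21/10",
  "AU/GU": "-3/5",
  "AU/UA": "-11/10",
  "AU/UG": "-7/5",
  "CG/AU": "-21/10",
  "CG/CG": "-33/10",
  "CG/GC": "-12/5",
  "CG/GU": "-7/5",
  "CG/UA": "-21/10",
  "CG/UG": "-21/10",
  "GC/AU": "-12/5",
  "GC/CG": "-17/5",
  "GC/GC": "-33/10",
  "GC/GU": "-3/2",
  "GC/UA": "-11/5",
  "GC/UG": "-5/2",
  "GU/AU": "-13/10",
  "GU/CG": "-5/2",
  "GU/GC": "-21/10",
  "GU/GU": "-1/2",
  "GU/UA": "-7/5",
  "GU/UG": "13/10",
  "UA/AU": "-13/10",
  "UA/CG": "-12/5",
  "UA/GC": "-21/10",
  "UA/GU": "-1",
  "UA/UA": "-9/10",
  "UA/UG": "-13/10",
  "UG/AU": "-1",
  "UG/CG": "-3/2",
  "UG/GC": "-7/5",
  "UG/GU": "3/10",
  "UG/UA": "-3/5",
  "UG/UG": "-1/2"
 },
 "hairpin_init": {
  "3": "27/5",
  "4": "28/5",
  "5": "57/10",
  "6": "27/5",
  "7": "6",
  "8": "11/2",
  "9": "32/5",
  "10": "13/2",
  "11": "33/5",
  "12": "67/10",
  "13": "34/5",
  "14": "69/10",
  "15": "69/10",
  "16": "7",
  "17": "71/10",
  "18": "71/10",
  "19": "36/5",
  "20": "36/5",
  "21": "73/10",
  "22": "73/10",
  "23": "37/5",
  "24": "37/5",
  "25": "15/2",
  "26": "15/2",
  "27": "15/2",
  "28": "38/5",
  "29": "38/5",
  "30": "77/10"
 },
 "internal_init": {
  "1": "19/5",
  "2": "14/5",
  "3": "16/5",
  "4": "18/5",
  "5": "4",
  "6": "22/5",
  "7": "23/5",
  "8": "47/10",
  "9": "24/5",
  "10": "49/10",
  "11": "5",
  "12": "51/10",
  "13": "26/5",
  "14": "26/5",
  "15": "53/10",
  "16": "27/5",
  "17": "27/5",
  "18": "11/2",
  "19": "11/2",
  "20": "28/5",
  "21": "28/5",
  "22": "57/10",
  "23": "57/10",
  "24": "29/5",
  "25": "29/5",
  "26": "29/5",
  "27": "59/10",
  "28": "59/10",
  "29": "59/10",
  "30": "6"
 },
 "terminal_au": "1/2",
 "extrapolation": {
  "base_size": 30,
  "coefficient": "11/10",
  "rule": "init(n) = init(30) + coefficient * ln(n/30), rounded to 0.1"
 }
}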