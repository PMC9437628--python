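{
 "1": 0.1,
 "2": 0.1,
 "3": 0.1,
 "4": 0.1,
 "5": 0.1,
 "6": 0.002,
 "7": 0.01,
 "8": 0.1,
 "9": 0.1,
 "10": 0.005,
 "11": 0.02,
 "12": 0.1,
 "13": 0.1,
 "14": 0.01,
 "15": 0.1,
 "16": 0.01,
 "17": 0.1,
 "18": 0.01,
 "19": 0.1,
 "20": 0.005,
 "21": 0.1,
 "22": 0.03,
 "23": 0.03,
 "24": 0.05,
 "25": 0.05,
 "26": 0.1,
 "27": 0.1,
 "28": 0.03,
 "29": 0.04,
 "30": 0.1,
 "31": 0.1,
 "32": 0.1,
 "33": 0.1,
 "34": 0.1,
 "35": 0.1,
 "36": 0.1,
 "37": 0.1,
 "38": 0.1,
 "39": 0.1,
 "40": 0.1,
 "41": 0.1,
 "42": 0.05,
 "43": 0.0303,
 "44": 0.1,
 "45": 0.02,
 "46": 0.1,
 "47": 0.1,
 "48": 0.1,
 "49": 0.01,
 "50": 0.01,
 "51": 0.01
}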