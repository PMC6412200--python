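manifest: ROT_INV
length: 90
entries:
- name: body_acc_mean_mag3
  reduce: norm
  sources:
  - 0
  - 1
  - 2
- name: body_acc_std_mag3
  reduce: norm
  sources:
  - 3
  - 4
  - 5
- name: body_acc_mad_mag3
  reduce: norm
  sources:
  - 6
  - 7
  - 8
- name: body_acc_max_mag3
  reduce: norm
  sources:
  - 9
  - 10
  - 11
- name: body_acc_min_mag3
  reduce: norm
  sources:
  - 12
  - 13
  - 14
- name: body_acc_energy_mag3
  reduce: sqrt_sum
  sources:
  - 15
  - 16
  - 17
- name: body_acc_iqr_mag3
  reduce: norm
  sources:
  - 18
  - 19
  - 20
- name: body_acc_entropy_mag3
  reduce: norm
  sources:
  - 21
  - 22
  - 23
- name: body_acc_ar0_mag3
  reduce: norm
  sources:
  - 24
  - 25
  - 26
- name: body_acc_ar1_mag3
  reduce: norm
  sources:
  - 27
  - 28
  - 29
- name: body_acc_ar2_mag3
  reduce: norm
  sources:
  - 30
  - 31
  - 32
- name: body_acc_ar3_mag3
  reduce: norm
  sources:
  - 33
  - 34
  - 35
- name: body_acc_sma_l2
  reduce: pass
  sources:
  - 117
- name: gravity_acc_mean_mag3
  reduce: norm
  sources:
  - 40
  - 41
  - 42
- name: gravity_acc_std_mag3
  reduce: norm
  sources:
  - 43
  - 44
  - 45
- name: gravity_acc_mad_mag3
  reduce: norm
  sources:
  - 46
  - 47
  - 48
- name: gravity_acc_max_mag3
  reduce: norm
  sources:
  - 49
  - 50
  - 51
- name: gravity_acc_min_mag3
  reduce: norm
  sources:
  - 52
  - 53
  - 54
- name: gravity_acc_energy_mag3
  reduce: sqrt_sum
  sources:
  - 55
  - 56
  - 57
- name: gravity_acc_iqr_mag3
  reduce: norm
  sources:
  - 58
  - 59
  - 60
- name: gravity_acc_entropy_mag3
  reduce: norm
  sources:
  - 61
  - 62
  - 63
- name: gravity_acc_ar0_mag3
  reduce: norm
  sources:
  - 64
  - 65
  - 66
- name: gravity_acc_ar1_mag3
  reduce: norm
  sources:
  - 67
  - 68
  - 69
- name: gravity_acc_ar2_mag3
  reduce: norm
  sources:
  - 70
  - 71
  - 72
- name: gravity_acc_ar3_mag3
  reduce: norm
  sources:
  - 73
  - 74
  - 75
- name: gravity_acc_sma_l2
  reduce: pass
  sources:
  - 120
- name: body_jerk_mean_mag3
  reduce: norm
  sources:
  - 77
  - 78
  - 79
- name: body_jerk_std_mag3
  reduce: norm
  sources:
  - 80
  - 81
  - 82
- name: body_jerk_mad_mag3
  reduce: norm
  sources:
  - 83
  - 84
  - 85
- name: body_jerk_max_mag3
  reduce: norm
  sources:
  - 86
  - 87
  - 88
- name: body_jerk_min_mag3
  reduce: norm
  sources:
  - 89
  - 90
  - 91
- name: body_jerk_energy_mag3
  reduce: sqrt_sum
  sources:
  - 92
  - 93
  - 94
- name: body_jerk_iqr_mag3
  reduce: norm
  sources:
  - 95
  - 96
  - 97
- name: body_jerk_entropy_mag3
  reduce: norm
  sources:
  - 98
  - 99
  - 100
- name: body_jerk_ar0_mag3
  reduce: norm
  sources:
  - 101
  - 102
  - 103
- name: body_jerk_ar1_mag3
  reduce: norm
  sources:
  - 104
  - 105
  - 106
- name: body_jerk_ar2_mag3
  reduce: norm
  sources:
  - 107
  - 108
  - 109
- name: body_jerk_ar3_mag3
  reduce: norm
  sources:
  - 110
  - 111
  - 112
- name: body_jerk_sma_l2
  reduce: pass
  sources:
  - 123
- name: mag_body_acc_mean
  reduce: pass
  sources:
  - 117
- name: mag_body_acc_std
  reduce: pass
  sources:
  - 118
- name: mag_body_acc_energy
  reduce: pass
  sources:
  - 119
- name: mag_gravity_acc_mean
  reduce: pass
  sources:
  - 120
- name: mag_gravity_acc_std
  reduce: pass
  sources:
  - 121
- name: mag_gravity_acc_energy
  reduce: pass
  sources:
  - 122
- name: mag_body_jerk_mean
  reduce: pass
  sources:
  - 123
- name: mag_body_jerk_std
  reduce: pass
  sources:
  - 124
- name: mag_body_jerk_energy
  reduce: pass
  sources:
  - 125
- name: f_body_acc_mean_mag3
  reduce: norm
  sources:
  - 126
  - 127
  - 128
- name: f_body_acc_std_mag3
  reduce: norm
  sources:
  - 129
  - 130
  - 131
- name: f_body_acc_mad_mag3
  reduce: norm
  sources:
  - 132
  - 133
  - 134
- name: f_body_acc_max_mag3
  reduce: norm
  sources:
  - 135
  - 136
  - 137
- name: f_body_acc_min_mag3
  reduce: norm
  sources:
  - 138
  - 139
  - 140
- name: f_body_acc_energy_mag3
  reduce: sqrt_sum
  sources:
  - 141
  - 142
  - 143
- name: f_body_acc_iqr_mag3
  reduce: norm
  sources:
  - 144
  - 145
  - 146
- name: f_body_acc_entropy_mag3
  reduce: norm
  sources:
  - 147
  - 148
  - 149
- name: f_body_acc_max_freq_ind_mag3
  reduce: norm
  sources:
  - 150
  - 151
  - 152
- name: f_body_acc_mean_freq_mag3
  reduce: norm
  sources:
  - 153
  - 154
  - 155
- name: f_body_acc_skewness_f_mag3
  reduce: norm
  sources:
  - 156
  - 157
  - 158
- name: f_body_acc_kurtosis_f_mag3
  reduce: norm
  sources:
  - 159
  - 160
  - 161
- name: f_body_acc_sma
  reduce: pass
  sources:
  - 162
- name: f_body_acc_band0_mag3
  reduce: sqrt_sum
  sources:
  - 166
  - 167
  - 168
- name: f_body_acc_band1_mag3
  reduce: sqrt_sum
  sources:
  - 169
  - 170
  - 171
- name: f_body_acc_band2_mag3
  reduce: sqrt_sum
  sources:
  - 172
  - 173
  - 174
- name: f_body_acc_band3_mag3
  reduce: sqrt_sum
  sources:
  - 175
  - 176
  - 177
- name: f_body_acc_band4_mag3
  reduce: sqrt_sum
  sources:
  - 178
  - 179
  - 180
- name: f_body_acc_band5_mag3
  reduce: sqrt_sum
  sources:
  - 181
  - 182
  - 183
- name: f_body_acc_band6_mag3
  reduce: sqrt_sum
  sources:
  - 184
  - 185
  - 186
- name: f_body_acc_band7_mag3
  reduce: sqrt_sum
  sources:
  - 187
  - 188
  - 189
- name: f_body_jerk_mean_mag3
  reduce: norm
  sources:
  - 190
  - 191
  - 192
- name: f_body_jerk_std_mag3
  reduce: norm
  sources:
  - 193
  - 194
  - 195
- name: f_body_jerk_mad_mag3
  reduce: norm
  sources:
  - 196
  - 197
  - 198
- name: f_body_jerk_max_mag3
  reduce: norm
  sources:
  - 199
  - 200
  - 201
- name: f_body_jerk_min_mag3
  reduce: norm
  sources:
  - 202
  - 203
  - 204
- name: f_body_jerk_energy_mag3
  reduce: sqrt_sum
  sources:
  - 205
  - 206
  - 207
- name: f_body_jerk_iqr_mag3
  reduce: norm
  sources:
  - 208
  - 209
  - 210
- name: f_body_jerk_entropy_mag3
  reduce: norm
  sources:
  - 211
  - 212
  - 213
- name: f_body_jerk_max_freq_ind_mag3
  reduce: norm
  sources:
  - 214
  - 215
  - 216
- name: f_body_jerk_mean_freq_mag3
  reduce: norm
  sources:
  - 217
  - 218
  - 219
- name: f_body_jerk_skewness_f_mag3
  reduce: norm
  sources:
  - 220
  - 221
  - 222
- name: f_body_jerk_kurtosis_f_mag3
  reduce: norm
  sources:
  - 223
  - 224
  - 225
- name: f_body_jerk_sma
  reduce: pass
  sources:
  - 226
- name: f_body_jerk_band0_mag3
  reduce: sqrt_sum
  sources:
  - 230
  - 231
  - 232
- name: f_body_jerk_band1_mag3
  reduce: sqrt_sum
  sources:
  - 233
  - 234
  - 235
- name: f_body_jerk_band2_mag3
  reduce: sqrt_sum
  sources:
  - 236
  - 237
  - 238
- name: f_body_jerk_band3_mag3
  reduce: sqrt_sum
  sources:
  - 239
  - 240
  - 241
- name: f_body_jerk_band4_mag3
  reduce: sqrt_sum
  sources:
  - 242
  - 243
  - 244
- name: f_body_jerk_band5_mag3
  reduce: sqrt_sum
  sources:
  - 245
  - 246
  - 247
- name: f_body_jerk_band6_mag3
  reduce: sqrt_sum
  sources:
  - 248
  - 249
  - 250
- name: f_body_jerk_band7_mag3
  reduce: sqrt_sum
  sources:
  - 251
  - 252
  - 253
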