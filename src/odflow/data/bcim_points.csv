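code,name,lat,lon,macroregion
292740,Salvador,-12.97177,-38.50811,East
293330,Vitória da Conquista,-14.86614,-40.83942,Southwest
290160,Anagé,-14.61229,-41.13579,Southwest
291080,Encruzilhada,-15.53103,-40.90952,Southwest
291480,Itabuna,-14.78852,-39.27987,South
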