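excerpt_id,artist,song,block,complexity,avg_liking,is_warmup
e01,Bonnie Raitt,Circle dance,4,2.625,51.37,False
e02,Air,New Star In The Sky,1,3.125,55.07,False
e03,Bo Kaspers Orkester,Valjer dig,3,3.5,50.80,False
e04,Bo Kaspers Orkester,Kvarter,2,3.75,48.40,False
e05,Magnus Edholm Combo,She's Within,4,4,56.24,False
e06,Genesis,7-8,3,4.125,50.51,False
e07,Santana,El Farol,2,4.375,60.78,False
e08,Bill Bergman,From Now On,4,4.625,54.38,False
e09,Jonas Knutsson Band,Lemet-Lemet Anna-Kirste,2,4.875,51.08,False
e10,David Sanborn,The Dream,2,5.125,57.76,False
e11,Nils Landgren Funk Unit,Rock it,3,5.5,48.73,False
e12,Kenny G,Sade,4,5.75,56.99,False
e13,Jean-Luc Ponty,Happy Robots,1,5.875,54.12,False
e14,Bill Bergman,The Night begins,3,6,50.32,False
e15,Bill Bergman,Midnight Sax Theme,4,6.125,43.14,False
e16,Roine Stolt,The Flower King,1,6.25,58.85,False
e17,Trio con X,Pass it On,2,6.375,46.54,False
e18,Trio con X,Chakas dans,3,6.5,43.69,False
e19,Greger Wikberg Trio,Svedbergs Massage,3,6.75,49.26,False
e20,"L Coryell, S Smith & T Coster",First things first,4,6.875,44.00,False
e21,Dave Weckl,Here and There,2,7.25,48.81,False
e22,Transatlantic,All of the Above,1,7.375,44.45,False
e23,Roine Stolt,The Magic Circus of Zeb,4,7.5,47.12,False
e24,Dave Weckl,Tower of Inspiration,3,8,47.30,False
e25,"L Coryell, S Smith & T Coster",Bubba,4,8.125,46.68,False
e26,Janne Schaffer,Bromma Express,2,8.25,52.41,False
e27,Bela Fleck & The Flecktones,Vix 9,1,8.375,57.44,False
e28,Janne Schaffer,Hot Days and Summer Nights,3,8.5,47.98,False
e29,Itchy Fingers,7.50 (only saxophone part),2,8.625,37.98,False
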